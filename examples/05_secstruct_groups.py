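"""Secondary structure of mature N-termini: shortest vs longest MTSs.

Selects the ten records with the shortest and ten with the longest
targeting signals per well-sampled species, and compares helix, strand
and disorder proportions over the first and second 50 mature residues
with a Kruskal-Wallis test.
"""

from mtsprofile import generate_dataset
from mtsprofile.secstruct import compare_groups, select_extreme_mts_groups, window_ss_proportions
from mtsprofile.windows import WindowSpec

dataset, annotations = generate_dataset(seed=42)
short, long_ = select_extreme_mts_groups(dataset, "Hsap", k=10)
print("short-MTS group lengths:", sorted(len(r.mts_seq) for r in short))
print("long-MTS  group lengths:", sorted(len(r.mts_seq) for r in long_))

window = WindowSpec(1, 50, "truncate")
for metric, idx in (("helix", 0), ("strand", 1), ("disorder", 2)):
    sv = [window_ss_proportions(annotations[r.record_id], window)[idx] for r in short]
    lv = [window_ss_proportions(annotations[r.record_id], window)[idx] for r in long_]
    h, p = compare_groups(sv, lv)
    print(f"{metric:9s} 1-50aa  mean short={sum(sv)/len(sv):.3f}  "
          f"mean long={sum(lv)/len(lv):.3f}  KW H={h:.3f}  p={p:.3f}")

print(
    "\nThe synthetic annotations are independent of MTS length, so H should be"
    "\nsmall and p large: this run is a null check of the comparison machinery."
)
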