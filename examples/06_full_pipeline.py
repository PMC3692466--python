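"""The whole pipeline in one call: dataset -> TSV report bundle.

Equivalent to `mtsprofile simulate` + `mtsprofile analyze` on the shell.
"""

import tempfile
from pathlib import Path

from mtsprofile import generate_dataset
from mtsprofile.pipeline import AnalysisConfig, analyze_dataset, write_bundle

dataset, annotations = generate_dataset(seed=42)
out = Path(tempfile.mkdtemp(prefix="mtsprofile_"))
config = AnalysisConfig(out_dir=out)
bundle = analyze_dataset(dataset, annotations, config)
write_bundle(bundle, out, config.pka_set)

print(f"status: {bundle.status}")
print(f"report bundle in {out}:")
for path in sorted(out.iterdir()):
    print(f"  {path.name:40s} {path.stat().st_size:6d} bytes")
print("\nmanifest:")
print(bundle.manifest)
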