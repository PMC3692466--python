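"""Secondary-structure annotations of mature sequences.

Annotations are consumed, never predicted: each mature chain carries a
per-residue string over {H, E, L} (helix, strand, other) plus a parallel
disorder mask over {D, .}.  The module computes windowed structure
proportions and compares the mature sequences attached to the shortest
versus the longest targeting signals of a species with a Kruskal–Wallis
test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import stats as _stats
from .seqio import Dataset
from .windows import WindowSpec, nterm_window

__all__ = [
    "SecStructAnnotation",
    "read_annotations",
    "write_annotations",
    "window_ss_proportions",
    "select_extreme_mts_groups",
    "compare_groups",
    "default_group_size",
]

logger = logging.getLogger(__name__)

SS_STATES = frozenset("HEL")
DISORDER_STATES = frozenset("D.")


@dataclass(frozen=True)
class SecStructAnnotation:
    record_id: str
    ss: str  # over {H, E, L}
    disorder: str  # over {D, .}

    def __post_init__(self) -> None:
        if len(self.ss) != len(self.disorder):
            raise ValueError(
                f"{self.record_id}: ss length {len(self.ss)} != disorder length {len(self.disorder)}"
            )
        bad = set(self.ss) - SS_STATES
        if bad:
            raise ValueError(f"{self.record_id}: invalid ss state(s) {sorted(bad)}")
        bad = set(self.disorder) - DISORDER_STATES
        if bad:
            raise ValueError(f"{self.record_id}: invalid disorder state(s) {sorted(bad)}")


def read_annotations(
    path: str | Path, dataset: Dataset | None = None
) -> dict[str, SecStructAnnotation]:
    """Load a record_id/ss/disorder TSV keyed by record_id.

    When *dataset* is given, each annotation must match the length of the
    record's mature sequence.  An empty file yields an empty collection
    (the secondary-structure stage is then skipped with a warning).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0 or not path.read_text().strip():
        logger.warning("annotation file %s is empty; stage will be skipped", path)
        return {}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("record_id", "ss", "disorder"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    by_id = {r.record_id: r for r in dataset} if dataset is not None else None
    out: dict[str, SecStructAnnotation] = {}
    for row in df.itertuples(index=False):
        ann = SecStructAnnotation(row.record_id, row.ss, row.disorder)
        if ann.record_id in out:
            raise ValueError(f"duplicate annotation for {ann.record_id!r}")
        if by_id is not None and ann.record_id in by_id:
            expect = len(by_id[ann.record_id].mature_seq)
            if len(ann.ss) != expect:
                raise ValueError(
                    f"{ann.record_id}: annotation length {len(ann.ss)} != "
                    f"mature sequence length {expect}"
                )
        out[ann.record_id] = ann
    return out


def write_annotations(
    annotations: dict[str, SecStructAnnotation], path: str | Path
) -> None:
    rows = [
        {"record_id": a.record_id, "ss": a.ss, "disorder": a.disorder}
        for a in annotations.values()
    ]
    pd.DataFrame(rows, columns=["record_id", "ss", "disorder"]).to_csv(
        path, sep="\t", index=False
    )


def window_ss_proportions(
    a: SecStructAnnotation, w: WindowSpec
) -> tuple[float, float, float] | None:
    """(helix, strand, disorder) fractions over the window, truncating.

    Returns None when the window lies entirely beyond the annotation.
    """
    truncating = WindowSpec(w.start, w.end, "truncate")
    ss_win = nterm_window(a.ss, truncating)
    if ss_win is None or not ss_win:
        return None
    dis_win = a.disorder[w.start - 1 : w.start - 1 + len(ss_win)]
    n = len(ss_win)
    return (
        ss_win.count("H") / n,
        ss_win.count("E") / n,
        dis_win.count("D") / n,
    )


def default_group_size(n_species_records: int) -> int:
    """10 extreme records for well-sampled species (>= 80), else 5."""
    return 10 if n_species_records >= 80 else 5


def select_extreme_mts_groups(
    dataset: Dataset, species: str, k: int
) -> tuple[list, list]:
    """The *k* records with shortest and with longest MTS, per species.

    Ties in MTS length are broken by record_id so the selection is a
    deterministic function of (dataset, species, k); the two groups are
    disjoint (requires 2k <= subset size).
    """
    subset = [r for r in dataset if r.species == species]
    if 2 * k > len(subset):
        raise ValueError(
            f"need 2k={2 * k} records but species {species!r} has {len(subset)}"
        )
    ranked = sorted(subset, key=lambda r: (len(r.mts_seq), r.record_id))
    return ranked[:k], ranked[-k:]


def compare_groups(
    short_values: list[float], long_values: list[float]
) -> tuple[float, float]:
    """Kruskal–Wallis H and p between the short- and long-MTS groups."""
    if len(short_values) < 2 or len(long_values) < 2:
        raise ValueError("each group needs at least 2 values")
    h, _, p = _stats.kruskal_wallis([short_values, long_values])
    return h, p
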