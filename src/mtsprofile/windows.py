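"""Fixed N-terminal windows of the mature sequence.

Coordinates are 1-based inclusive and counted from the first residue
after the MTS cleavage site.  Two policies govern short sequences:
``require_full`` drops a record from a window's statistics when the
mature chain does not span the window (the default for the windowed
correlation tables, where a truncated window is not comparable), while
``truncate`` keeps whatever overlap exists.
"""

from __future__ import annotations

from dataclasses import dataclass

from .physchem import NINE_GROUPS, ReducedAlphabetMap, composition
from .seqio import ProteinRecord

__all__ = ["WindowSpec", "nterm_window", "windowed_group_fraction", "parse_windows"]


@dataclass(frozen=True)
class WindowSpec:
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive
    policy: str = "require_full"

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid window {self.start}-{self.end}")
        if self.policy not in ("require_full", "truncate"):
            raise ValueError(f"unknown policy {self.policy!r}")

    @property
    def label(self) -> str:
        return f"{self.start}-{self.end}"


def parse_windows(text: str, policy: str = "require_full") -> list[WindowSpec]:
    """Parse ``"1-40,41-80"`` into WindowSpecs."""
    out = []
    for chunk in text.split(","):
        start, end = chunk.strip().split("-")
        out.append(WindowSpec(int(start), int(end), policy))
    return out


def nterm_window(seq: str, w: WindowSpec) -> str | None:
    """Residues ``start..end`` of *seq*, or None when the window is absent."""
    if not seq:
        raise ValueError("empty sequence")
    if w.policy == "require_full" and len(seq) < w.end:
        return None
    if w.start > len(seq):
        return None
    return seq[w.start - 1 : min(w.end, len(seq))]


def windowed_group_fraction(
    record: ProteinRecord,
    w: WindowSpec,
    group: str,
    alphabet: ReducedAlphabetMap = NINE_GROUPS,
) -> float | None:
    """Group fraction over the mature-sequence window, or None when absent.

    Absent values are dropped pairwise from downstream correlations.
    """
    if group not in alphabet.groups:
        raise KeyError(f"unknown group code {group!r}")
    window = nterm_window(record.mature_seq, w)
    if window is None:
        return None
    return composition(window, alphabet)[group]
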