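"""Datasets of species-labelled MTS / mature-sequence pairs.

The canonical on-disk form is a TSV with columns ``record_id``,
``species``, ``gene_id``, ``accession``, ``mts_seq``, ``mature_seq``
(``.`` marks a missing optional field).  A FASTA dialect of full
precursors is also read: the description line must carry
``cleavage=<k>``, the 1-based index of the last MTS residue.

Records are validated on load (alphabet, unknown-residue fraction,
unique ids); failures are collected into a per-record rejection report
rather than aborting the read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .physchem import STANDARD_RESIDUES, UNKNOWN_RESIDUES

__all__ = [
    "ProteinRecord",
    "Dataset",
    "Rejection",
    "DEFAULT_SPECIES",
    "read_dataset",
    "write_dataset",
    "split_full_sequence",
    "write_table",
    "read_table",
]

DEFAULT_SPECIES: tuple[str, ...] = ("Hsap", "Mmus", "Scer", "Atha", "Osat")

TSV_COLUMNS = ("record_id", "species", "gene_id", "accession", "mts_seq", "mature_seq")

_VALID = STANDARD_RESIDUES | UNKNOWN_RESIDUES


@dataclass(frozen=True)
class ProteinRecord:
    """One species-labelled (MTS, mature) pair."""

    record_id: str
    species: str
    mts_seq: str
    mature_seq: str
    gene_id: str | None = None
    accession: str | None = None

    def validate(self, max_unknown_frac: float = 0.05) -> str | None:
        """Return a rejection reason, or None when the record is valid."""
        if not self.record_id:
            return "empty record_id"
        if not self.species:
            return "empty species"
        for part_name, seq in (("mts_seq", self.mts_seq), ("mature_seq", self.mature_seq)):
            if not seq:
                return f"empty {part_name}"
            bad = sorted({c for c in seq if c not in _VALID})
            if bad:
                return f"invalid residue {''.join(bad)!r} in {part_name}"
            unknown = sum(seq.count(u) for u in UNKNOWN_RESIDUES)
            if unknown / len(seq) > max_unknown_frac:
                return (
                    f"{part_name} has {unknown}/{len(seq)} unknown residues "
                    f"(> {max_unknown_frac:.0%} allowed)"
                )
        return None


@dataclass(frozen=True)
class Rejection:
    record_id: str
    reason: str


@dataclass
class Dataset:
    """Ordered collection of validated ProteinRecords."""

    records: list[ProteinRecord] = field(default_factory=list)
    provenance: str = ""
    rejections: list[Rejection] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.species] = counts.get(rec.species, 0) + 1
        return counts

    def subset(self, species: str) -> "Dataset":
        return Dataset(
            records=[r for r in self.records if r.species == species],
            provenance=f"{self.provenance} [subset {species}]",
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "record_id": r.record_id,
                "species": r.species,
                "gene_id": r.gene_id or ".",
                "accession": r.accession or ".",
                "mts_seq": r.mts_seq,
                "mature_seq": r.mature_seq,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(TSV_COLUMNS))


def split_full_sequence(full_seq: str, cleavage_pos: int) -> tuple[str, str]:
    """Split a precursor at the 1-based index of the last MTS residue."""
    if not 1 <= cleavage_pos < len(full_seq):
        raise ValueError(
            f"cleavage_pos {cleavage_pos} out of range for length {len(full_seq)}"
        )
    return full_seq[:cleavage_pos], full_seq[cleavage_pos:]


def _build(
    raw: list[dict[str, str | None]],
    provenance: str,
    species: tuple[str, ...] | None,
    max_unknown_frac: float,
) -> Dataset:
    seen: set[str] = set()
    ds = Dataset(provenance=provenance)
    for row in raw:
        rec = ProteinRecord(
            record_id=str(row["record_id"]).strip(),
            species=str(row["species"]).strip(),
            mts_seq=str(row["mts_seq"]).strip().upper(),
            mature_seq=str(row["mature_seq"]).strip().upper(),
            gene_id=row.get("gene_id") or None,
            accession=row.get("accession") or None,
        )
        if rec.record_id in seen:
            raise ValueError(f"duplicate record_id {rec.record_id!r}")
        seen.add(rec.record_id)
        reason = rec.validate(max_unknown_frac)
        if reason is None and species is not None and rec.species not in species:
            reason = f"species {rec.species!r} not in configured set"
        if reason is None:
            ds.records.append(rec)
        else:
            ds.rejections.append(Rejection(rec.record_id, reason))
    return ds


def read_dataset(
    path: str | Path,
    format: str = "tsv",
    species: tuple[str, ...] | None = None,
    max_unknown_frac: float = 0.05,
) -> Dataset:
    """Load and validate a dataset of MTS/mature pairs.

    Parameters
    ----------
    path
        TSV file (canonical columns) or, with ``format="fasta_pair"``, a
        FASTA of full precursors whose descriptions carry ``cleavage=<k>``.
    species
        Optional closed set of species tags; records outside it are
        rejected.  ``None`` accepts any tag.
    max_unknown_frac
        Maximum tolerated fraction of unknown residues (X,B,Z,U,O,J) per
        sequence part.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty input file: {path}")

    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = [c for c in ("record_id", "species", "mts_seq", "mature_seq") if c not in df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {', '.join(missing)}")
        raw = [
            {k: (None if v in (".", "") else v) for k, v in row.items()}
            for row in df.to_dict("records")
        ]
        # required fields must not be treated as missing
        for src, row in zip(df.to_dict("records"), raw):
            for col in ("record_id", "species", "mts_seq", "mature_seq"):
                row[col] = src[col]
    elif format == "fasta_pair":
        raw = []
        for seqrec in SeqIO.parse(str(path), "fasta"):
            desc = seqrec.description
            cleave = None
            for token in desc.replace(",", " ").split():
                if token.startswith("cleavage="):
                    cleave = int(token.split("=", 1)[1])
            if cleave is None:
                raise ValueError(f"record {seqrec.id!r}: no cleavage=<int> in description")
            sp = "."
            for token in desc.split():
                if token.startswith("species="):
                    sp = token.split("=", 1)[1]
            mts, mature = split_full_sequence(str(seqrec.seq).upper(), cleave)
            raw.append(
                {
                    "record_id": seqrec.id,
                    "species": sp,
                    "gene_id": None,
                    "accession": None,
                    "mts_seq": mts,
                    "mature_seq": mature,
                }
            )
        if not raw:
            raise ValueError(f"no FASTA records in {path}")
    else:
        raise ValueError(f"unknown format {format!r}")

    if not raw:
        raise ValueError(f"no records in {path}")
    return _build(raw, provenance=str(path), species=species, max_unknown_frac=max_unknown_frac)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, sep="\t", index=False)


def write_table(
    table: pd.DataFrame,
    path: str | Path,
    sig_digits: int = 6,
    index: bool = True,
    comment: str | None = None,
) -> None:
    """Write a labelled rectangular table as TSV (header row included).

    Floats are printed at *sig_digits* significant digits; an optional
    ``# comment`` line (e.g. the active pKa set) precedes the header.
    """
    if table.columns.duplicated().any() or (index and table.index.duplicated().any()):
        raise ValueError("row/column labels must be unique")
    buf = io.StringIO()
    if comment:
        buf.write(f"# {comment}\n")
    table.to_csv(buf, sep="\t", index=index, float_format=f"%.{sig_digits}g")
    Path(path).write_text(buf.getvalue())


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, comment="#")
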