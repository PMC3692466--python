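"""End-to-end orchestration: dataset -> property tables -> report bundle.

A run computes, per species and pooled: the 12-variable physicochemical
profile of every MTS and mature sequence, the MTS x mature Spearman
correlation grid with significance classes, PCA summaries of the
property tables, windowed N-terminal correlations (MTS length and MTS
charge against the acidic-residue fraction of fixed mature-sequence
windows), and — when annotations are supplied — helix/strand/disorder
comparisons between the shortest- and longest-MTS groups.  All outputs
are TSV plus a plain-text manifest; re-running on identical inputs
produces byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .physchem import PROPERTY_NAMES, ChargeModel, NINE_GROUPS, sequence_properties
from .secstruct import (
    SecStructAnnotation,
    compare_groups,
    default_group_size,
    read_annotations,
    select_extreme_mts_groups,
    window_ss_proportions,
)
from .seqio import Dataset, read_dataset, write_table
from .stats import CorrelationMatrix, PCAResult, correlation_matrix, pca, spearman
from .windows import WindowSpec, windowed_group_fraction

__all__ = ["AnalysisConfig", "ReportBundle", "analyze_dataset", "run_full_analysis"]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    dataset_path: str | Path | None = None
    annotations_path: str | Path | None = None
    dataset_format: str = "tsv"
    out_dir: str | Path | None = None
    pH: float = 7.5
    pka_set: str = "bjellqvist"
    include_termini: bool = True
    windows: tuple[WindowSpec, ...] = (
        WindowSpec(1, 40, "require_full"),
        WindowSpec(41, 80, "require_full"),
    )
    ss_windows: tuple[WindowSpec, ...] = (
        WindowSpec(1, 50, "truncate"),
        WindowSpec(51, 100, "truncate"),
    )
    extreme_group_k: int | None = None  # None: 10 if species n >= 80 else 5
    min_n: int = 5
    retention: str | int = "kaiser"
    max_unknown_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.pH < 14.0:
            raise ValueError(f"pH out of (0,14): {self.pH}")


@dataclass
class ReportBundle:
    species: pd.Series  # record_id -> species tag
    props_mts: pd.DataFrame
    props_mature: pd.DataFrame
    correlations: dict[str, CorrelationMatrix]
    pca_mts: dict[str, PCAResult]
    pca_combined: PCAResult | None
    windowed: pd.DataFrame
    ss_comparison: pd.DataFrame | None
    manifest: str
    warnings: list[str] = field(default_factory=list)

    @property
    def status(self) -> str:
        return "warnings" if self.warnings else "ok"


def properties_table(
    dataset: Dataset,
    part: str,
    pH: float = 7.5,
    model: ChargeModel | None = None,
    include_termini: bool = True,
) -> pd.DataFrame:
    """12-variable profile per record for one sequence part ('mts'|'mature')."""
    if part not in ("mts", "mature"):
        raise ValueError(f"part must be 'mts' or 'mature', got {part!r}")
    if model is None:
        model = ChargeModel.from_name()
    rows = {}
    for rec in dataset:
        seq = rec.mts_seq if part == "mts" else rec.mature_seq
        rows[rec.record_id] = sequence_properties(
            seq, pH=pH, alphabet=NINE_GROUPS, model=model, include_termini=include_termini
        ).as_dict()
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(PROPERTY_NAMES))
    frame.index.name = "record_id"
    return frame


def _windowed_table(
    dataset: Dataset,
    props_mts: pd.DataFrame,
    windows: tuple[WindowSpec, ...],
    min_n: int,
) -> pd.DataFrame:
    """Per-species (+pooled) correlations of MTS length/charge vs windowed
    acidic-residue fraction of the mature N-terminus."""
    species_tags = sorted({r.species for r in dataset})
    rows = []
    for w in windows:
        frac = pd.Series(
            {r.record_id: windowed_group_fraction(r, w, "d") for r in dataset},
            dtype=float,
        )
        for grouping in ["pooled"] + species_tags:
            ids = [
                r.record_id
                for r in dataset
                if grouping == "pooled" or r.species == grouping
            ]
            for var in ("length", "charge_pH"):
                cell = spearman(
                    props_mts.loc[ids, var].to_numpy(),
                    frac.loc[ids].to_numpy(),
                    min_n=min_n,
                )
                rows.append(
                    {
                        "grouping": grouping,
                        "window": w.label,
                        "mts_variable": var,
                        "rho": cell.rho,
                        "p": cell.p,
                        "n": cell.n,
                        "sig_class": cell.sig_class,
                    }
                )
    return pd.DataFrame(rows)


def _ss_table(
    dataset: Dataset,
    annotations: dict[str, SecStructAnnotation],
    ss_windows: tuple[WindowSpec, ...],
    k_override: int | None,
) -> pd.DataFrame:
    """Short- vs long-MTS comparison of windowed structure proportions."""
    annotated = Dataset(
        records=[r for r in dataset if r.record_id in annotations],
        provenance=dataset.provenance + " [annotated]",
    )
    rows = []
    metric_index = {"helix": 0, "strand": 1, "disorder": 2}
    for species, n_sp in sorted(annotated.species_counts().items()):
        k = k_override if k_override is not None else default_group_size(n_sp)
        if 2 * k > n_sp:
            logger.warning("species %s: %d annotated records < 2k=%d; skipped", species, n_sp, 2 * k)
            continue
        short, long_ = select_extreme_mts_groups(annotated, species, k)
        for w in ss_windows:
            values: dict[str, dict[str, list[float]]] = {
                m: {"short": [], "long": []} for m in metric_index
            }
            for group_name, group in (("short", short), ("long", long_)):
                for rec in group:
                    props = window_ss_proportions(annotations[rec.record_id], w)
                    if props is None:
                        continue
                    for metric, mi in metric_index.items():
                        values[metric][group_name].append(props[mi])
            for metric in metric_index:
                sv, lv = values[metric]["short"], values[metric]["long"]
                if len(sv) < 2 or len(lv) < 2:
                    continue
                h, p = compare_groups(sv, lv)
                rows.append(
                    {
                        "species": species,
                        "window": w.label,
                        "metric": metric,
                        "k": k,
                        "n_short": len(sv),
                        "n_long": len(lv),
                        "median_short": float(np.median(sv)),
                        "median_long": float(np.median(lv)),
                        "H": h,
                        "p": p,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "species", "window", "metric", "k", "n_short", "n_long",
            "median_short", "median_long", "H", "p",
        ],
    )


def _manifest(
    config: AnalysisConfig, dataset: Dataset, bundle_warnings: list[str]
) -> str:
    counts = dataset.species_counts()
    lines = [
        f"mtsprofile {__version__}",
        f"dataset: {dataset.provenance}",
        f"records: {len(dataset)}",
        "species_counts: "
        + ", ".join(f"{sp}={n}" for sp, n in sorted(counts.items())),
        f"rejected_records: {len(dataset.rejections)}",
        f"pka_set: {config.pka_set}",
        f"pH: {config.pH}",
        f"termini_ionized: {config.include_termini}",
        f"windows: {','.join(w.label for w in config.windows)} (policy {config.windows[0].policy})",
        f"ss_windows: {','.join(w.label for w in config.ss_windows)} (policy {config.ss_windows[0].policy})",
        f"min_pairs_per_cell: {config.min_n}",
        f"pca_retention: {config.retention}",
        f"extreme_group_k: {config.extreme_group_k if config.extreme_group_k is not None else 'auto (10 if n>=80 else 5)'}",
        f"status: {'warnings' if bundle_warnings else 'ok'}",
    ]
    lines += [f"warning: {w}" for w in bundle_warnings]
    return "\n".join(lines) + "\n"


def analyze_dataset(
    dataset: Dataset,
    annotations: dict[str, SecStructAnnotation] | None = None,
    config: AnalysisConfig | None = None,
) -> ReportBundle:
    """Run every analysis stage on an in-memory dataset.

    Stage failures are logged, recorded as warnings and skip dependent
    outputs; they never abort the remaining stages.
    """
    if config is None:
        config = AnalysisConfig()
    model = ChargeModel.from_name(config.pka_set)
    warnings: list[str] = []

    species = pd.Series(
        {r.record_id: r.species for r in dataset}, name="species", dtype=str
    )
    for sp, n in sorted(dataset.species_counts().items()):
        logger.info("species %s: %d records", sp, n)

    props_mts = properties_table(dataset, "mts", config.pH, model, config.include_termini)
    props_mature = properties_table(
        dataset, "mature", config.pH, model, config.include_termini
    )

    correlations: dict[str, CorrelationMatrix] = {}
    pca_mts: dict[str, PCAResult] = {}
    pca_combined: PCAResult | None = None
    groupings = ["pooled"] + sorted(species.unique())
    for grouping in groupings:
        ids = species.index if grouping == "pooled" else species.index[species == grouping]
        try:
            correlations[grouping] = correlation_matrix(
                props_mts.loc[ids], props_mature.loc[ids], grouping, config.min_n
            )
            if not any(
                c.computed for c in correlations[grouping].cells.values()
            ):
                warnings.append(
                    f"correlations[{grouping}]: no cell reached min_n={config.min_n}"
                )
        except Exception as err:  # stage isolation
            logger.exception("correlation stage failed for %s", grouping)
            warnings.append(f"correlations[{grouping}] failed: {err}")
        try:
            pca_mts[grouping] = pca(props_mts.loc[ids], config.retention)
        except Exception as err:
            logger.exception("MTS PCA failed for %s", grouping)
            warnings.append(f"pca_mts[{grouping}] failed: {err}")
    try:
        combined = props_mts.add_prefix("mts_").join(props_mature.add_prefix("mat_"))
        pca_combined = pca(combined, config.retention)
    except Exception as err:
        logger.exception("combined PCA failed")
        warnings.append(f"pca_combined failed: {err}")

    try:
        windowed = _windowed_table(dataset, props_mts, config.windows, config.min_n)
        if windowed["sig_class"].eq("none").all() and windowed["n"].lt(config.min_n).all():
            warnings.append("windowed correlations: all cells below min_n")
    except Exception as err:
        logger.exception("windowed stage failed")
        warnings.append(f"windowed stage failed: {err}")
        windowed = pd.DataFrame()

    ss_comparison: pd.DataFrame | None = None
    if annotations:
        try:
            ss_comparison = _ss_table(
                dataset, annotations, config.ss_windows, config.extreme_group_k
            )
        except Exception as err:
            logger.exception("secondary-structure stage failed")
            warnings.append(f"secstruct stage failed: {err}")
    else:
        logger.info("no annotations supplied; secondary-structure stage skipped")

    manifest = _manifest(config, dataset, warnings)
    return ReportBundle(
        species=species,
        props_mts=props_mts,
        props_mature=props_mature,
        correlations=correlations,
        pca_mts=pca_mts,
        pca_combined=pca_combined,
        windowed=windowed,
        ss_comparison=ss_comparison,
        manifest=manifest,
        warnings=warnings,
    )


def write_bundle(bundle: ReportBundle, out_dir: str | Path, pka_set: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    note = f"pKa set: {pka_set}"
    for part, frame in (("mts", bundle.props_mts), ("mature", bundle.props_mature)):
        write_table(
            frame.join(bundle.species), out / f"properties_{part}.tsv", comment=note
        )
    if bundle.correlations:
        long = pd.concat(
            [m.to_long_frame() for m in bundle.correlations.values()],
            ignore_index=True,
        )
        write_table(long, out / "correlations_long.tsv", index=False, comment=note)
        for grouping, m in bundle.correlations.items():
            write_table(m.rho_frame(), out / f"correlation_rho_{grouping}.tsv", comment=note)
            write_table(m.p_frame(), out / f"correlation_p_{grouping}.tsv", comment=note)
    for grouping, result in bundle.pca_mts.items():
        write_table(result.summary_frame(), out / f"pca_mts_{grouping}_summary.tsv")
        write_table(result.loadings, out / f"pca_mts_{grouping}_loadings.tsv")
    if bundle.pca_combined is not None:
        write_table(bundle.pca_combined.summary_frame(), out / "pca_combined_pooled_summary.tsv")
        write_table(bundle.pca_combined.loadings, out / "pca_combined_pooled_loadings.tsv")
    if len(bundle.windowed):
        write_table(bundle.windowed, out / "windowed_correlations.tsv", index=False, comment=note)
    if bundle.ss_comparison is not None and len(bundle.ss_comparison):
        write_table(bundle.ss_comparison, out / "secstruct_comparison.tsv", index=False)
    (out / "manifest.txt").write_text(bundle.manifest)


def run_full_analysis(config: AnalysisConfig) -> ReportBundle:
    """Load inputs per *config*, analyze, and write the report bundle."""
    if config.dataset_path is None:
        raise ValueError("config.dataset_path is required")
    dataset = read_dataset(
        config.dataset_path,
        format=config.dataset_format,
        max_unknown_frac=config.max_unknown_frac,
    )
    annotations = None
    if config.annotations_path is not None:
        annotations = read_annotations(config.annotations_path, dataset)
    bundle = analyze_dataset(dataset, annotations, config)
    if config.out_dir is not None:
        write_bundle(bundle, config.out_dir, config.pka_set)
    return bundle
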