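"""Label-free protein quantification and two-proteome comparison.

The abundance proxy is the exponentially modified protein abundance index
(emPAI), ``10**(n_observed / n_observable) - 1``, where ``n_observed`` is the
number of distinct sequenced peptides for a protein and ``n_observable`` the
number of theoretically observable tryptic peptides.  On top of it this module
provides replicate merging, set-algebra partitioning of two proteomes into
shared and cell-line-specific fractions, signed fold-changes for the shared
fraction, three-way differential classification, replicate Pearson agreement
and a dynamic-range summary.

All proteins are keyed by canonical uppercase gene symbol: every downstream
join (interaction networks, annotation terms) is symbol-level.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProteinQuant",
    "ProteomeProfile",
    "DifferentialRecord",
    "PartitionResult",
    "compute_empai",
    "merge_replicates",
    "fold_change",
    "classify_differential",
    "partition",
    "replicate_pearson",
    "dynamic_range",
    "compare_profiles",
    "fold_band_counts",
    "read_quant_table",
    "profile_from_table",
    "write_differential_table",
    "write_partition_report",
]

Label = Literal["over", "under", "unaltered"]


def normalize_symbol(symbol: str) -> str:
    """Canonicalize a gene symbol: strip whitespace, uppercase."""
    return str(symbol).strip().upper()


def compute_empai(n_observed: int, n_observable: int) -> float:
    """emPAI = 10**(n_observed / n_observable) - 1.

    Parameters
    ----------
    n_observed : int
        Number of sequenced (observed) peptides, >= 0.
    n_observable : int
        Number of theoretically observable tryptic peptides, >= 1.
    """
    if n_observable < 1:
        raise ValueError(f"n_observable must be >= 1, got {n_observable}")
    if n_observed < 0:
        raise ValueError(f"n_observed must be >= 0, got {n_observed}")
    return float(10.0 ** (n_observed / n_observable) - 1.0)


def merge_replicates(
    values: Sequence[float], mode: Literal["detected", "all"] = "detected"
) -> float:
    """Merge per-replicate emPAI values into one abundance.

    ``detected`` (default) averages over replicates where the protein was
    observed (value > 0); ``all`` averages over every replicate, counting
    absences as zero.  A protein absent from every replicate merges to 0.
    """
    if len(values) == 0:
        raise ValueError("cannot merge an empty replicate list")
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("emPAI values must be non-negative")
    if mode == "all":
        return float(arr.mean())
    if mode != "detected":
        raise ValueError(f"unknown merge mode: {mode!r}")
    detected = arr[arr > 0]
    return float(detected.mean()) if detected.size else 0.0


def fold_change(empai_a: float, empai_b: float) -> float:
    """Signed fold-change between two abundances.

    Returns ``+empai_a/empai_b`` when condition A is at least as abundant,
    ``-empai_b/empai_a`` otherwise, so ``|fold| >= 1`` always and the sign
    points at the higher condition (negative = higher in B).  Ties return
    +1.0 by convention.
    """
    if empai_a <= 0 or empai_b <= 0:
        raise ValueError(
            "fold_change requires positive abundances on both sides "
            f"(got {empai_a}, {empai_b}); cell-line-specific proteins have "
            "no finite fold and are handled by partition()"
        )
    if empai_a >= empai_b:
        return float(empai_a / empai_b)
    return float(-empai_b / empai_a)


def classify_differential(fold: float, threshold: float = 2.0) -> Label:
    """Map a signed fold onto {over, under, unaltered} at a |fold| threshold."""
    if threshold <= 1:
        raise ValueError(f"threshold must be > 1, got {threshold}")
    if fold > threshold:
        return "over"
    if fold < -threshold:
        return "under"
    return "unaltered"


@dataclass(frozen=True)
class ProteinQuant:
    """One protein in one replicate of one cell line."""

    accession: str
    n_observed: int
    n_observable: int
    empai: float
    replicate_id: str

    def __post_init__(self) -> None:
        if self.n_observed < 0:
            raise ValueError("n_observed must be >= 0")
        if self.n_observable < 1:
            raise ValueError("n_observable must be >= 1")
        if self.empai < 0:
            raise ValueError("empai must be >= 0")
        if (self.empai == 0) != (self.n_observed == 0):
            raise ValueError("empai must be 0 exactly when n_observed is 0")


@dataclass
class ProteomeProfile:
    """A merged proteome for one cell line.

    ``records`` maps accession -> merged emPAI; ``replicate_matrix`` holds the
    per-replicate emPAI values (rows = proteins seen in at least one
    replicate, columns = replicates, absences as 0).
    """

    cell_line: str
    records: dict[str, float]
    replicate_matrix: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.records.values()):
            raise ValueError("merged emPAI values must be non-negative")

    @property
    def accessions(self) -> set[str]:
        return set(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class DifferentialRecord:
    """A shared protein's paired abundances, signed fold and class label."""

    accession: str
    empai_a: float
    empai_b: float
    fold: float
    label: Label


@dataclass(frozen=True)
class PartitionResult:
    """Venn decomposition of two proteomes on accession keys."""

    shared: frozenset[str]
    specific_a: frozenset[str]
    specific_b: frozenset[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "total_a": len(self.shared) + len(self.specific_a),
            "total_b": len(self.shared) + len(self.specific_b),
            "shared": len(self.shared),
            "specific_a": len(self.specific_a),
            "specific_b": len(self.specific_b),
        }


def partition(profile_a: ProteomeProfile, profile_b: ProteomeProfile) -> PartitionResult:
    """Split two proteomes into shared / A-specific / B-specific sets."""
    for profile in (profile_a, profile_b):
        if len(profile) == 0:
            raise ValueError(f"profile {profile.cell_line!r} is empty")
    a, b = profile_a.accessions, profile_b.accessions
    return PartitionResult(
        shared=frozenset(a & b),
        specific_a=frozenset(a - b),
        specific_b=frozenset(b - a),
    )


def compare_profiles(
    profile_a: ProteomeProfile,
    profile_b: ProteomeProfile,
    threshold: float = 2.0,
) -> list[DifferentialRecord]:
    """Fold-change and classify every shared protein (sorted by accession).

    A shared protein quantified as zero in either profile is a data error:
    presence in a profile implies at least one observed peptide.
    """
    part = partition(profile_a, profile_b)
    records = []
    for acc in sorted(part.shared):
        ea, eb = profile_a.records[acc], profile_b.records[acc]
        if ea <= 0 or eb <= 0:
            raise ValueError(
                f"shared protein {acc} has a non-positive merged emPAI "
                f"({ea}, {eb}); shared proteins must be quantified in both"
            )
        f = fold_change(ea, eb)
        records.append(
            DifferentialRecord(acc, ea, eb, f, classify_differential(f, threshold))
        )
    return records


def fold_band_counts(
    records: Iterable[DifferentialRecord],
    bands: Sequence[float] = (1.0, 1.5, 2.0),
) -> dict[str, int]:
    """Count shared proteins per |fold| band (half-open; last band unbounded)."""
    edges = list(bands) + [np.inf]
    counts = {}
    folds = [abs(r.fold) for r in records]
    for lo, hi in zip(edges[:-1], edges[1:]):
        key = f"{lo:g}-{hi:g}" if np.isfinite(hi) else f">{lo:g}"
        counts[key] = sum(lo <= f < hi for f in folds)
    return counts


def replicate_pearson(replicate_matrix: pd.DataFrame) -> float:
    """Mean pairwise Pearson r between replicate columns.

    Pairs involving a constant (zero-variance) column are skipped with a
    warning; if every pair is skipped the result is undefined.
    """
    mat = np.asarray(replicate_matrix, dtype=float)
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 replicates")
    if mat.shape[0] < 3:
        raise ValueError("need at least 3 proteins")
    rs = []
    for i in range(mat.shape[1]):
        for j in range(i + 1, mat.shape[1]):
            x, y = mat[:, i], mat[:, j]
            if np.std(x) == 0 or np.std(y) == 0:
                warnings.warn(
                    f"replicate pair ({i}, {j}) skipped: zero variance",
                    stacklevel=2,
                )
                continue
            rs.append(stats.pearsonr(x, y).statistic)
    if not rs:
        raise ValueError("all replicate pairs had zero variance")
    return float(np.mean(rs))


def dynamic_range(profile: ProteomeProfile) -> dict[str, float]:
    """Spread of merged abundances: log2(max/min), with ratio and log10.

    Zero-emPAI entries are excluded with a warning (the ratio is otherwise
    unbounded).  Returns ``{"log2": ..., "log10": ..., "ratio": ...}``.
    """
    values = np.array([v for v in profile.records.values()], dtype=float)
    if (values == 0).any():
        warnings.warn(
            f"{int((values == 0).sum())} zero-emPAI proteins excluded from "
            "dynamic range",
            stacklevel=2,
        )
        values = values[values > 0]
    if values.size == 0:
        raise ValueError("no positive emPAI values")
    ratio = float(values.max() / values.min())
    return {"log2": float(np.log2(ratio)), "log10": float(np.log10(ratio)), "ratio": ratio}


# ---------------------------------------------------------------------------
# I/O

QUANT_COLUMNS = ["accession", "gene_symbol", "replicate_id", "n_observed", "n_observable"]


def read_quant_table(path: str | Path) -> pd.DataFrame:
    """Read a per-replicate quant table (TSV, or XLSX with the same columns).

    Required columns: accession, gene_symbol, replicate_id, n_observed,
    n_observable.  An ``empai`` column is optional and computed from the
    counts when absent.  Symbols are canonicalized on load.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep="\t")
    missing = [c for c in QUANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = df.copy()
    df["gene_symbol"] = df["gene_symbol"].map(normalize_symbol)
    if "empai" not in df.columns:
        df["empai"] = [
            compute_empai(int(o), int(p))
            for o, p in zip(df["n_observed"], df["n_observable"])
        ]
    return df


def profile_from_table(
    df: pd.DataFrame,
    cell_line: str,
    merge_mode: Literal["detected", "all"] = "detected",
) -> ProteomeProfile:
    """Build a merged :class:`ProteomeProfile` from a per-replicate table.

    Symbol collisions after normalization keep the max-emPAI record per
    (symbol, replicate) and are reported via a warning.
    """
    dup = df.duplicated(subset=["gene_symbol", "replicate_id"], keep=False)
    if dup.any():
        collided = sorted(df.loc[dup, "gene_symbol"].unique())
        warnings.warn(
            f"{cell_line}: symbol collisions after normalization for "
            f"{collided}; keeping max emPAI per replicate",
            stacklevel=2,
        )
        df = (
            df.sort_values("empai")
            .drop_duplicates(subset=["gene_symbol", "replicate_id"], keep="last")
        )
    mat = (
        df.pivot_table(
            index="gene_symbol", columns="replicate_id", values="empai", fill_value=0.0
        )
        .sort_index()
    )
    merged = {
        sym: merge_replicates(row.to_numpy(), mode=merge_mode)
        for sym, row in mat.iterrows()
    }
    return ProteomeProfile(cell_line=cell_line, records=merged, replicate_matrix=mat)


def write_differential_table(
    records: Sequence[DifferentialRecord], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "accession": r.accession,
                "empai_a": r.empai_a,
                "empai_b": r.empai_b,
                "fold": r.fold,
                "label": r.label,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def write_partition_report(
    part: PartitionResult, tsv_path: str | Path, json_path: str | Path
) -> None:
    """Write the membership TSV and a JSON summary of the Venn counts."""
    rows = (
        [{"accession": a, "set": "shared"} for a in sorted(part.shared)]
        + [{"accession": a, "set": "specific_a"} for a in sorted(part.specific_a)]
        + [{"accession": a, "set": "specific_b"} for a in sorted(part.specific_b)]
    )
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    Path(json_path).write_text(json.dumps(part.counts, indent=2) + "\n")
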