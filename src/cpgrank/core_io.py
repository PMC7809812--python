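"""Data model and readers/writers for beta matrices, sample sheets and probe annotation.

All pipeline stages operate on three tables:

``BetaMatrix``
    probes × samples methylation fractions in [0, 1] (``NaN`` = missing).
``SampleSheet``
    one row per sample: subject, timepoint, disease, treatment, response,
    OS/PFS columns and an optional technical-replicate group used for
    batch concordance checks.
``ProbeAnnotation``
    genomic position of each probe plus (optionally) the gene it is
    annotated to, the gene strand and the TSS coordinate. Coordinates are
    1-based and inclusive throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input table violates a documented invariant."""


class FormatError(ValueError):
    """Raised when a file cannot be parsed into the expected layout."""


# ---------------------------------------------------------------------------
# BetaMatrix


@dataclass
class BetaMatrix:
    """Probes × samples matrix of methylation beta values.

    ``values`` is a float DataFrame indexed by probe id with sample ids as
    columns; missing measurements are NaN. Construction validates the
    [0, 1] bound and id uniqueness.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if not isinstance(df, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame")
        df = df.astype(float)
        _check_unique(df.index, "probe")
        _check_unique(df.columns, "sample")
        arr = df.to_numpy()
        bad = np.where(~np.isnan(arr) & ((arr < 0.0) | (arr > 1.0)))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValidationError(
                f"beta value {arr[i, j]!r} outside [0, 1] at probe "
                f"{df.index[i]!r}, sample {df.columns[j]!r}"
            )
        df.index.name = "probe_id"
        object.__setattr__(self, "values", df)

    # -- convenience accessors ------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, probes: Iterable[str]) -> "BetaMatrix":
        probes = pd.Index(probes)
        missing = probes.difference(self.values.index)
        if len(missing):
            raise KeyError(f"unknown probes: {list(missing[:5])}")
        return BetaMatrix(self.values.loc[probes])

    def subset_samples(self, samples: Iterable[str]) -> "BetaMatrix":
        samples = pd.Index(samples)
        missing = samples.difference(self.values.columns)
        if len(missing):
            raise KeyError(f"unknown samples: {list(missing[:5])}")
        return BetaMatrix(self.values[samples])

    def drop_high_missing_probes(self, max_missing_frac: float = 0.2) -> "BetaMatrix":
        """Drop probes with more than ``max_missing_frac`` missing values.

        The remaining missings are handled pairwise-complete by the
        statistics layer.
        """
        frac = self.values.isna().mean(axis=1)
        return BetaMatrix(self.values.loc[frac <= max_missing_frac])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BetaMatrix):
            return NotImplemented
        a, b = self.values, other.values
        return (
            a.index.equals(b.index)
            and a.columns.equals(b.columns)
            and np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9, equal_nan=True)
        )


def _check_unique(idx: pd.Index, what: str) -> None:
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise ValidationError(f"duplicate {what} id {dup!r}")


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    """Read a TSV beta matrix (first column probe ids, header = sample ids).

    Cells are numeric or the token ``NA`` for a missing measurement.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header or "\t" not in header and header.strip() == "":
        raise FormatError(f"{path}: missing or empty header line")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
        df = df.astype(float)
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BetaMatrix(df)


def write_beta_matrix(m: BetaMatrix, path: str | Path) -> None:
    """Write the matrix as TSV with missing values spelled ``NA``."""
    m.values.to_csv(path, sep="\t", na_rep="NA", index_label="probe_id")


# ---------------------------------------------------------------------------
# SampleSheet

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "subject_id",
    "timepoint",
    "disease",
    "treatment",
    "response",
    "os_months",
    "os_event",
    "pfs_months",
    "pfs_event",
    "reference_replicate_group",
]

TIMEPOINTS = {"diagnosis", "followup"}
DISEASES = {"MDS", "sAML", "control"}
TREATMENTS = {"AZA", "other", "none"}
RESPONSES = {"responder", "nonresponder", "unknown"}


@dataclass
class SampleSheet:
    """Clinical covariates and survival endpoints, one row per sample."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing_cols = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"sample sheet missing columns: {missing_cols}")
        _check_unique(pd.Index(df["sample_id"]), "sample")
        for col, allowed in [
            ("timepoint", TIMEPOINTS),
            ("disease", DISEASES),
            ("treatment", TREATMENTS),
            ("response", RESPONSES),
        ]:
            bad = set(df[col].dropna()) - allowed
            if bad:
                raise ValidationError(f"invalid {col} value(s): {sorted(bad)}")
        for col in ("os_months", "pfs_months"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if (vals.dropna() < 0).any():
                offender = df.loc[vals < 0, "sample_id"].iloc[0]
                raise ValidationError(f"negative {col} for sample {offender!r}")
            df[col] = vals
        for col in ("os_event", "pfs_event"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad_mask = ~vals.isin([0, 1]) & vals.notna()
            if bad_mask.any():
                offender = df.loc[bad_mask, "sample_id"].iloc[0]
                raise ValidationError(f"{col} not in {{0,1}} for sample {offender!r}")
            df[col] = vals
        df = df.reset_index(drop=True)
        object.__setattr__(self, "table", df)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    def select(self, **conditions) -> pd.DataFrame:
        """Rows matching equality conditions, e.g. ``select(treatment='AZA')``."""
        df = self.table
        for col, val in conditions.items():
            df = df[df[col] == val]
        return df

    def replicate_groups(self) -> dict[str, list[str]]:
        """Replicate-group label -> sample ids (groups with ≥2 samples)."""
        col = self.table["reference_replicate_group"]
        out: dict[str, list[str]] = {}
        for label, sub in self.table[col.notna() & (col != "")].groupby(
            "reference_replicate_group"
        ):
            if len(sub) >= 2:
                out[str(label)] = list(sub["sample_id"])
        return out


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ProbeAnnotation

ANNOTATION_COLUMNS = ["probe_id", "chrom", "pos", "gene_id", "strand", "tss_pos"]


@dataclass
class ProbeAnnotation:
    """Genomic placement of probes and their (optional) gene/TSS annotation.

    A probe may appear on several rows when annotated to several genes.
    ``gene_id``, ``strand`` and ``tss_pos`` are empty together for
    intergenic probes.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing_cols = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"probe annotation missing columns: {missing_cols}")
        df["pos"] = pd.to_numeric(df["pos"])
        if (df["pos"] < 1).any():
            offender = df.loc[df["pos"] < 1, "probe_id"].iloc[0]
            raise ValidationError(f"pos < 1 for probe {offender!r}")
        df["gene_id"] = df["gene_id"].replace("", np.nan)
        has_gene = df["gene_id"].notna()
        df["tss_pos"] = pd.to_numeric(df["tss_pos"], errors="coerce")
        if (df.loc[has_gene, "tss_pos"].isna()).any() or (
            df.loc[has_gene, "tss_pos"].dropna() < 1
        ).any():
            offender = df.loc[has_gene & (df["tss_pos"].isna() | (df["tss_pos"] < 1)), "probe_id"].iloc[0]
            raise ValidationError(f"invalid tss_pos for annotated probe {offender!r}")
        strand_ok = df["strand"].isin(["+", "-"])
        if (has_gene & ~strand_ok).any():
            offender = df.loc[has_gene & ~strand_ok, "probe_id"].iloc[0]
            raise ValidationError(f"annotated probe {offender!r} lacks a valid strand")
        object.__setattr__(self, "table", df.reset_index(drop=True))


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    return ProbeAnnotation(df)


def write_probe_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# Batch concordance via duplicated reference samples


@dataclass
class ConcordancePair:
    group: str
    sample_a: str
    sample_b: str
    n_shared_probes: int
    pearson_r: float
    flagged: bool = field(default=False)


def reference_concordance(
    m: BetaMatrix, sheet: SampleSheet, threshold: float = 0.99
) -> list[ConcordancePair]:
    """Pearson correlation between technical-replicate reference samples.

    High-throughput methylation studies run the same reference DNA on every
    batch; replicate profiles should be essentially identical, so a low
    correlation flags a batch effect. Returns one record per within-group
    pair; pairs with r below ``threshold`` carry ``flagged=True``. An empty
    list is returned when the sheet defines no replicate groups.
    """
    report: list[ConcordancePair] = []
    for group, samples in sheet.replicate_groups().items():
        present = [s for s in samples if s in m.sample_ids]
        for a, b in itertools.combinations(present, 2):
            x = m.values[a].to_numpy()
            y = m.values[b].to_numpy()
            keep = ~np.isnan(x) & ~np.isnan(y)
            n = int(keep.sum())
            if n < 3:
                raise ValidationError(
                    f"replicate pair ({a!r}, {b!r}) shares only {n} non-missing "
                    "probes; correlation undefined"
                )
            r = float(np.corrcoef(x[keep], y[keep])[0, 1])
            report.append(ConcordancePair(group, a, b, n, r, flagged=r < threshold))
    return report
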