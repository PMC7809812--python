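"""Promoter-window assignment and gene-level summaries of filtered sites.

A gene's promoter is the interval from 2000 bp upstream to 500 bp
downstream of its transcription start site, strand-mirrored so "upstream"
always means 5' of the gene. Probes are assigned to every promoter whose
window contains them (promoters of neighbouring genes overlap in real
manifests), and per-gene counts of filtered hyper-/hypomethylated probes
feed the ≥1-site and ≥4-site gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from cpgrank.core_io import ProbeAnnotation, ValidationError

UPSTREAM = 2000
DOWNSTREAM = 500


def promoter_window(tss_pos: int, strand: str) -> tuple[int, int]:
    """1-based inclusive promoter interval around a TSS.

    ``+`` strand: [tss − 2000, tss + 500]; ``−`` strand mirrored:
    [tss − 500, tss + 2000]. The lower bound is clipped at 1.
    """
    if tss_pos < 1:
        raise ValidationError(f"tss_pos must be >= 1, got {tss_pos}")
    if strand == "+":
        lo, hi = tss_pos - UPSTREAM, tss_pos + DOWNSTREAM
    elif strand == "-":
        lo, hi = tss_pos - DOWNSTREAM, tss_pos + UPSTREAM
    else:
        raise ValidationError(f"invalid strand {strand!r}")
    return max(lo, 1), hi


def assign_probes_to_promoters(ann: ProbeAnnotation) -> pd.DataFrame:
    """Probe → gene promoter membership.

    Returns a DataFrame with one row per (probe, gene) pair where the
    probe's position falls inside the gene's promoter window on the same
    chromosome. Columns: probe_id, gene_id, strand, window_start,
    window_end. Order of the input rows does not affect membership.
    """
    df = ann.table
    genes = df.loc[df["gene_id"].notna(), ["gene_id", "chrom", "strand", "tss_pos"]]
    genes = genes.drop_duplicates("gene_id")
    wins = genes.apply(
        lambda r: promoter_window(int(r["tss_pos"]), r["strand"]), axis=1
    )
    genes = genes.assign(
        window_start=[w[0] for w in wins], window_end=[w[1] for w in wins]
    )
    probes = df[["probe_id", "chrom", "pos"]].drop_duplicates("probe_id")
    merged = probes.merge(genes, on="chrom")
    inside = (merged["pos"] >= merged["window_start"]) & (
        merged["pos"] <= merged["window_end"]
    )
    out = merged.loc[
        inside, ["probe_id", "gene_id", "strand", "window_start", "window_end"]
    ]
    return out.sort_values(["gene_id", "probe_id"], kind="mergesort").reset_index(
        drop=True
    )


@dataclass
class PromoterGeneLists:
    """Gene lists at the standard reporting thresholds."""

    hyper_ge1: list[str]
    hypo_ge1: list[str]
    hyper_ge4: list[str]


def summarize_promoters(
    hyper: pd.DataFrame | pd.Index,
    hypo: pd.DataFrame | pd.Index,
    membership: pd.DataFrame,
) -> tuple[pd.DataFrame, PromoterGeneLists]:
    """Per-gene promoter counts of filtered differential probes.

    ``hyper``/``hypo`` are the threshold-filter outputs (or their probe
    indexes). Returns a summary table (gene_id, strand, window, number of
    promoter probes, hyper and hypo counts among them) and the gene lists
    with ≥1 hypermethylated, ≥1 hypomethylated and ≥4 hypermethylated
    promoter probes.
    """
    hyper_ids = set(hyper.index if isinstance(hyper, pd.DataFrame) else hyper)
    hypo_ids = set(hypo.index if isinstance(hypo, pd.DataFrame) else hypo)

    memb = membership.copy()
    memb["is_hyper"] = memb["probe_id"].isin(hyper_ids)
    memb["is_hypo"] = memb["probe_id"].isin(hypo_ids)
    summary = (
        memb.groupby("gene_id")
        .agg(
            strand=("strand", "first"),
            window_start=("window_start", "first"),
            window_end=("window_end", "first"),
            n_probes_in_window=("probe_id", "size"),
            n_hyper=("is_hyper", "sum"),
            n_hypo=("is_hypo", "sum"),
        )
        .reset_index()
        .sort_values("gene_id", kind="mergesort")
        .reset_index(drop=True)
    )
    lists = PromoterGeneLists(
        hyper_ge1=list(summary.loc[summary["n_hyper"] >= 1, "gene_id"]),
        hypo_ge1=list(summary.loc[summary["n_hypo"] >= 1, "gene_id"]),
        hyper_ge4=list(summary.loc[summary["n_hyper"] >= 4, "gene_id"]),
    )
    return summary, lists
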