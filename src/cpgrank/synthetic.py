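"""Synthetic 450K-like cohorts with a ground-truth channel.

The generator emulates the structure of a methylation-array study of
high-risk MDS/sAML patients treated with a hypomethylating agent:

* per-probe trimodal methylation states (unmethylated / hemimethylated /
  methylated), drawn per sample from a Beta distribution parameterized by
  (mean μ, precision ν) so values are bounded and realistically skewed;
* planted differentially methylated probes: one group's mean shifted by
  ``effect_delta`` (clipped to [0.02, 0.98]);
* a pair of duplicated reference samples carried alongside the cohort for
  batch-concordance checks;
* probe annotation placing a configurable fraction of probes inside the
  −2000/+500 bp promoter window of synthetic genes;
* censored exponential survival with a latent risk class whose hazard is
  multiplied by ``hazard_ratio``;
* follow-up samples with a global demethylation shift, mimicking the
  genome-wide beta decrease seen after azacitidine treatment.

Everything is driven by a single integer seed; identical configurations
produce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cpgrank.core_io import (
    BetaMatrix,
    ProbeAnnotation,
    SampleSheet,
    SAMPLE_SHEET_COLUMNS,
    ValidationError,
)

# Default mode means for the three canonical 450K beta modes.
MODE_MEANS = (0.1, 0.5, 0.85)

# Planted group means are kept inside this band so Beta(μν, (1−μ)ν) stays
# well defined and away from the boundary.
MEAN_CLIP = (0.02, 0.98)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated cohort.

    Defaults mirror a mid-sized single-center array study: ~75 patients
    split between azacitidine and other treatment plus a small healthy
    control arm, with a modest number of strongly shifted CpGs.
    """

    n_probes: int = 10_000
    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"MDS": 24, "sAML": 13, "control": 10}
    )
    frac_promoter_probes: float = 0.3
    planted_sites: int = 100
    effect_delta: float = 0.3
    precision_nu: float = 50.0
    mode_weights: tuple[float, float, float] = (0.45, 0.15, 0.40)
    hazard_ratio: float = 3.0
    baseline_hazard: float = 1.0 / 18.0  # events per month; median ~12.5 months
    censoring_rate: float = 0.25
    followup_demethylation: float = 0.1
    followup_noise_sd: float = 0.02
    frac_responders: float = 0.55
    n_reference_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.mode_weights) - 1.0) > 1e-9:
            raise ValidationError("mode_weights must sum to 1")
        if not (0 <= self.planted_sites <= self.n_probes):
            raise ValidationError("planted_sites must lie in [0, n_probes]")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValidationError("group sizes must be non-negative")
        if not -1.0 <= self.effect_delta <= 1.0:
            raise ValidationError("effect_delta must lie in [-1, 1]")
        if self.precision_nu <= 0:
            raise ValidationError("precision_nu must be positive")
        if not 0.0 <= self.frac_promoter_probes <= 1.0:
            raise ValidationError("frac_promoter_probes must lie in [0, 1]")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValidationError("censoring_rate must lie in [0, 1]")
        if self.hazard_ratio <= 0:
            raise ValidationError("hazard_ratio must be positive")


@dataclass
class GroundTruth:
    """Truth channel emitted next to the simulated tables.

    ``group_means`` has one row per probe with the true Beta means used for
    the patient and control arms; ``latent_class`` maps subject id to the
    high/low-risk survival class; ``responder_probes`` are the sites whose
    shift separates responders from non-responders.
    """

    planted_probe_ids: list[str]
    responder_probes: list[str]
    group_means: pd.DataFrame
    latent_class: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        df = self.group_means.copy()
        df["planted"] = df.index.isin(self.planted_probe_ids)
        df["responder_signal"] = df.index.isin(self.responder_probes)
        return df


def _shift_means(mu: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Shift probe means by ±delta, flipping direction rather than clipping.

    The shift direction reverses for probes where the requested direction
    would leave [0.02, 0.98], so the realized effect magnitude equals
    |delta| wherever feasible; only when neither direction fits is the
    value clipped.
    """
    lo, hi = MEAN_CLIP
    shifted = mu + delta
    flip = (shifted < lo) | (shifted > hi)
    shifted[flip] = mu[flip] - delta[flip]
    return np.clip(shifted, lo, hi)


def _draw_betas(rng: np.random.Generator, mu: np.ndarray, nu: float) -> np.ndarray:
    mu = np.clip(mu, *MEAN_CLIP)
    return rng.beta(mu * nu, (1.0 - mu) * nu)


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[BetaMatrix, SampleSheet, ProbeAnnotation, GroundTruth]:
    """Simulate a diagnosis-timepoint cohort with planted differential probes.

    The planted shift is applied to the *patient* arms relative to controls
    (first half of the planted set hypermethylated in patients, second half
    hypomethylated), and half of the planted set additionally separates
    responders from non-responders within the treated arm — so the same
    cohort exercises both the patients-vs-controls and the
    responder-vs-non-responder comparisons with known truth.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_probes
    probe_ids = np.array([f"cg{i:08d}" for i in range(n)])

    modes = rng.choice(3, size=n, p=np.asarray(cfg.mode_weights, dtype=float))
    base_mu = np.array(MODE_MEANS)[modes]

    planted = rng.choice(n, size=cfg.planted_sites, replace=False)
    planted.sort()
    sign = np.ones(cfg.planted_sites)
    sign[cfg.planted_sites // 2 :] = -1.0

    patient_mu = base_mu.copy()
    patient_mu[planted] = _shift_means(base_mu[planted], sign * cfg.effect_delta)

    # Half of the planted sites also carry a responder/non-responder contrast.
    resp_idx = planted[: cfg.planted_sites // 2]
    responder_mu = patient_mu.copy()
    nonresponder_mu = patient_mu.copy()
    nonresponder_mu[resp_idx] = _shift_means(
        patient_mu[resp_idx], -cfg.effect_delta * np.ones(len(resp_idx))
    )

    # ---- samples -----------------------------------------------------------
    rows: list[dict] = []
    columns: dict[str, np.ndarray] = {}
    subject_counter = 0
    latent_class: dict[str, str] = {}

    for disease, n_group in cfg.n_per_group.items():
        for _ in range(n_group):
            subject_counter += 1
            subject = f"subj{subject_counter:03d}"
            sample = f"{subject}_dx"
            if disease == "control":
                treatment, response = "none", "unknown"
                mu = base_mu
                os_months = os_event = pfs_months = pfs_event = np.nan
                risk = None
            else:
                treatment = "AZA" if rng.random() < 0.5 else "other"
                responder = rng.random() < cfg.frac_responders
                response = "responder" if responder else "nonresponder"
                mu = responder_mu if responder else nonresponder_mu
                # Latent survival class: non-responders enriched for high risk.
                high_risk = rng.random() < (0.25 if responder else 0.75)
                risk = "high" if high_risk else "low"
                hazard = cfg.baseline_hazard * (cfg.hazard_ratio if high_risk else 1.0)
                t_event = rng.exponential(1.0 / hazard)
                # Uniform censoring calibrated to the requested censoring rate.
                c_max = 2.0 / (cfg.baseline_hazard * max(cfg.censoring_rate, 1e-6))
                t_cens = rng.uniform(0, c_max)
                os_months = float(min(t_event, t_cens))
                os_event = int(t_event <= t_cens)
                t_prog = rng.exponential(1.0 / (hazard * 1.3))
                pfs_months = float(min(t_prog, t_cens))
                pfs_event = int(t_prog <= t_cens)
                latent_class[subject] = risk
            columns[sample] = _draw_betas(rng, mu, cfg.precision_nu)
            rows.append(
                dict(
                    sample_id=sample,
                    subject_id=subject,
                    timepoint="diagnosis",
                    disease=disease,
                    treatment=treatment,
                    response=response,
                    os_months=os_months,
                    os_event=os_event,
                    pfs_months=pfs_months,
                    pfs_event=pfs_event,
                    reference_replicate_group=np.nan,
                )
            )

    # Duplicated reference DNA measured in every batch: identical truth, tiny
    # technical jitter.
    ref_mu = _draw_betas(rng, base_mu, cfg.precision_nu)
    for k in range(cfg.n_reference_replicates):
        sample = f"ref_rep{k + 1}"
        jitter = rng.normal(0.0, 0.005, size=n)
        columns[sample] = np.clip(ref_mu + jitter, 0.0, 1.0)
        rows.append(
            dict(
                sample_id=sample,
                subject_id="reference",
                timepoint="diagnosis",
                disease="control",
                treatment="none",
                response="unknown",
                os_months=np.nan,
                os_event=np.nan,
                pfs_months=np.nan,
                pfs_event=np.nan,
                reference_replicate_group="ref",
            )
        )

    beta = BetaMatrix(pd.DataFrame(columns, index=probe_ids))
    sheet = SampleSheet(pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS))
    ann = _simulate_annotation(rng, probe_ids, cfg.frac_promoter_probes)

    truth = GroundTruth(
        planted_probe_ids=list(probe_ids[planted]),
        responder_probes=list(probe_ids[resp_idx]),
        group_means=pd.DataFrame(
            {
                "control_mean": base_mu,
                "patient_mean": patient_mu,
                "responder_mean": responder_mu,
                "nonresponder_mean": nonresponder_mu,
            },
            index=pd.Index(probe_ids, name="probe_id"),
        ),
        latent_class=latent_class,
    )
    return beta, sheet, ann, truth


def _simulate_annotation(
    rng: np.random.Generator, probe_ids: np.ndarray, frac_promoter: float
) -> ProbeAnnotation:
    """Lay probes on one synthetic chromosome; a fraction inside promoters.

    Genes are placed on a 100 kb grid with alternating strands. A promoter
    probe is dropped uniformly into its gene's −2000/+500 window (strand
    mirrored); the remainder are placed in gene bodies or intergenic space.
    """
    n = len(probe_ids)
    n_genes = max(1, n // 40)
    tss = 50_000 + 100_000 * np.arange(n_genes)
    strands = np.where(np.arange(n_genes) % 2 == 0, "+", "-")
    gene_ids = np.array([f"GENE{i:05d}" for i in range(n_genes)])

    is_promoter = rng.random(n) < frac_promoter
    gene_of_probe = rng.integers(0, n_genes, size=n)

    pos = np.empty(n, dtype=int)
    gene_col = np.full(n, np.nan, dtype=object)
    strand_col = np.full(n, np.nan, dtype=object)
    tss_col = np.full(n, np.nan)

    offsets = rng.integers(-2000, 501, size=n)
    for i in range(n):
        g = gene_of_probe[i]
        if is_promoter[i]:
            off = offsets[i]
            pos[i] = tss[g] + (off if strands[g] == "+" else -off)
        else:
            # Gene body / downstream: 1–40 kb past the TSS, outside the window.
            body = int(rng.integers(2_000, 40_000))
            pos[i] = tss[g] + (body if strands[g] == "+" else -body)
        gene_col[i] = gene_ids[g]
        strand_col[i] = strands[g]
        tss_col[i] = tss[g]
    pos = np.maximum(pos, 1)

    df = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": "chr1",
            "pos": pos,
            "gene_id": gene_col,
            "strand": strand_col,
            "tss_pos": tss_col,
        }
    )
    return ProbeAnnotation(df)


def simulate_followup(
    m: BetaMatrix,
    sheet: SampleSheet,
    cfg: SimulationConfig,
    subjects: Sequence[str] | None = None,
) -> tuple[BetaMatrix, SampleSheet]:
    """Append follow-up samples for treated subjects.

    Follow-up values are the subject's diagnosis values minus the global
    ``followup_demethylation`` shift plus Gaussian noise, clipped to [0, 1].
    Untreated subjects (treatment == 'none') receive noise only. The
    returned matrix and sheet contain both timepoints.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    table = sheet.table
    dx = table[table["timepoint"] == "diagnosis"].set_index("subject_id")
    if subjects is None:
        subjects = [
            s
            for s in dx.index
            if s != "reference" and dx.loc[s, "disease"] != "control"
        ]
    unknown = [s for s in subjects if s not in dx.index]
    if unknown:
        raise ValidationError(f"no diagnosis sample for subject(s) {unknown}")

    new_cols: dict[str, np.ndarray] = {}
    new_rows: list[dict] = []
    for subject in subjects:
        row = dx.loc[subject]
        base = m.values[row["sample_id"]].to_numpy()
        shift = cfg.followup_demethylation if row["treatment"] != "none" else 0.0
        noise = (
            rng.normal(0.0, cfg.followup_noise_sd, size=base.shape)
            if cfg.followup_noise_sd > 0
            else 0.0
        )
        new_cols[f"{subject}_fu"] = np.clip(base - shift + noise, 0.0, 1.0)
        rec = row.to_dict()
        rec.update(
            sample_id=f"{subject}_fu",
            subject_id=subject,
            timepoint="followup",
            reference_replicate_group=np.nan,
        )
        new_rows.append(rec)

    combined = pd.concat(
        [m.values, pd.DataFrame(new_cols, index=m.values.index)], axis=1
    )
    new_table = pd.concat(
        [table, pd.DataFrame(new_rows)[table.columns]], ignore_index=True
    )
    return BetaMatrix(combined), SampleSheet(new_table)


def samples_from_profile(
    mu: np.ndarray | pd.Series,
    probe_ids: Sequence[str],
    n_samples: int,
    precision_nu: float,
    seed: int,
    prefix: str = "s",
) -> BetaMatrix:
    """Draw new samples from a fixed per-probe mean profile.

    Useful for held-out samples of a known class or for a third, distinct
    latent profile (e.g. disease progression) that matches neither
    signature centroid.
    """
    rng = np.random.default_rng(seed)
    mu = np.asarray(mu, dtype=float)
    cols = {
        f"{prefix}{i + 1:03d}": _draw_betas(rng, mu, precision_nu)
        for i in range(n_samples)
    }
    return BetaMatrix(pd.DataFrame(cols, index=pd.Index(probe_ids, name="probe_id")))


def with_seed(cfg: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``cfg`` with a different seed."""
    return replace(cfg, seed=seed)
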