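"""Synthetic cohort generator with planted high-risk expression programs.

Emulates the statistical shape the training pipeline assumes: ~220 tumors,
two latent high-risk classes (~20% each) carrying distinct ~40-gene
expression programs and an elevated recurrence hazard, a large background
of uninformative genes, exponential failure times and administrative
right-censoring around a ~41-month median follow-up. The full planted
truth (per-sample class, per-gene role) is returned so every pipeline
stage can be scored against it.

Program 1 lowers its genes (split into epithelial-like and
proliferation-like blocks, mirroring a post-EMT, low-proliferation state);
program 2 raises its genes (a TGF-beta-like block of a hybrid
epithelial/mesenchymal state). Optionally, immune marker genes are
depleted in class high1 to emulate an immune-desert microenvironment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .characterize import IMMUNE_MARKER_PANEL
from .exceptions import ConfigError
from .io import write_clinical, write_expression

MARKER_GENES = tuple(g for gs in IMMUNE_MARKER_PANEL for g in gs.genes)


@dataclass
class SyntheticConfig:
    """Knobs of the planted-subgroup cohort simulator.

    Hazards are per month; ``effect_size`` is the mean program-gene shift
    in units of the residual sd; per-gene magnitudes vary uniformly within
    +/-50% of it so planted centroids are not flat.
    """

    n_samples: int = 220
    frac_high1: float = 0.20
    frac_high2: float = 0.20
    n_genes: int = 2000
    n_sig_genes_per_program: int = 40
    effect_size: float = 1.0
    baseline_hazard: float = 0.004
    hr_high1: float = 4.0
    hr_high2: float = 4.0
    followup_max_months: float = 60.0
    censor_admin_months: float = 41.0
    censor_jitter_months: float = 6.0
    noise_sd: float = 1.0
    immune_depletion_high1: float | None = None
    seed: int = 0

    def validate(self):
        if not (0 <= self.frac_high1 and 0 <= self.frac_high2
                and self.frac_high1 + self.frac_high2 < 1):
            raise ConfigError("class fractions must be >= 0 and sum to < 1")
        if self.n_samples < 1 or self.n_genes < 1:
            raise ConfigError("n_samples and n_genes must be positive")
        if 2 * self.n_sig_genes_per_program > self.n_genes:
            raise ConfigError("program genes exceed the gene universe")
        for name in ("baseline_hazard", "hr_high1", "hr_high2",
                     "followup_max_months", "censor_admin_months", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.censor_jitter_months < 0:
            raise ConfigError("censor_jitter_months must be >= 0")
        return self


@dataclass
class SyntheticCohort:
    expression: pd.DataFrame  # genes x samples, log2-like scale
    clinical: pd.DataFrame  # indexed by sample_id
    sample_truth: pd.DataFrame  # planted_class per sample
    gene_truth: pd.DataFrame  # role + planted shifts per gene
    config: SyntheticConfig

    def write(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_expression(self.expression, outdir / "expression.tsv")
        write_clinical(self.clinical.reset_index(), outdir / "clinical.tsv")
        self.sample_truth.to_csv(outdir / "sample_truth.tsv", sep="\t")
        self.gene_truth.to_csv(outdir / "gene_truth.tsv", sep="\t")

    def epithelial_marker_genes(self) -> list:
        """Planted epithelial-like genes (lost in class high1); used to give
        the trained subgroups a canonical order."""
        return list(self.gene_truth.index[self.gene_truth["role"] == "program1_epi"])


def simulate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw a cohort from the planted-program model; reproducible from seed."""
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)

    n, g = cfg.n_samples, cfg.n_genes
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    # --- gene roles: fixed blocks at the start of the id range -------------
    k = cfg.n_sig_genes_per_program
    gene_ids = [f"G{i + 1:05d}" for i in range(g)]
    roles = np.array(["noise"] * g, dtype=object)
    n_epi = k // 2
    roles[:n_epi] = "program1_epi"
    roles[n_epi:k] = "program1_prolif"
    roles[k:2 * k] = "program2"
    marker_rows = []
    if cfg.immune_depletion_high1 is not None:
        gene_ids = gene_ids + list(MARKER_GENES)
        marker_rows = list(MARKER_GENES)
        roles = np.concatenate([roles, ["marker"] * len(MARKER_GENES)])

    # --- planted per-gene shifts ------------------------------------------
    shift1 = np.zeros(len(gene_ids))
    shift2 = np.zeros(len(gene_ids))
    mag1 = cfg.effect_size * cfg.noise_sd * rng.uniform(0.5, 1.5, size=k)
    mag2 = cfg.effect_size * cfg.noise_sd * rng.uniform(0.5, 1.5, size=k)
    shift1[:k] = -mag1  # program 1 genes are lost in class high1
    shift2[k:2 * k] = +mag2  # program 2 genes are gained in class high2
    if marker_rows:
        shift1[g:] = cfg.immune_depletion_high1

    # --- sample classes ----------------------------------------------------
    p = [1 - cfg.frac_high1 - cfg.frac_high2, cfg.frac_high1, cfg.frac_high2]
    classes = rng.choice(["low", "high1", "high2"], size=n, p=p)

    # --- expression --------------------------------------------------------
    baseline = rng.normal(7.0, 1.5, size=len(gene_ids))
    values = baseline[:, None] + rng.normal(0.0, cfg.noise_sd,
                                            size=(len(gene_ids), n))
    values[:, classes == "high1"] += shift1[:, None]
    values[:, classes == "high2"] += shift2[:, None]
    expression = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                              columns=sample_ids)

    # --- survival ----------------------------------------------------------
    hr = np.where(classes == "high1", cfg.hr_high1,
                  np.where(classes == "high2", cfg.hr_high2, 1.0))
    hazard = cfg.baseline_hazard * hr
    t_fail = rng.exponential(1.0 / hazard)
    jitter = rng.uniform(-cfg.censor_jitter_months, cfg.censor_jitter_months,
                         size=n) if cfg.censor_jitter_months > 0 else np.zeros(n)
    t_censor = np.minimum(cfg.followup_max_months,
                          np.maximum(1e-3, cfg.censor_admin_months + jitter))
    event = (t_fail <= t_censor).astype(int)
    time = np.where(event == 1, t_fail, t_censor)

    clinical = pd.DataFrame({
        "sample_id": sample_ids,
        "time_months": time,
        "event": event,
        "treatment_flag": "none",
    }).set_index("sample_id")

    sample_truth = pd.DataFrame(
        {"planted_class": classes},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    gene_truth = pd.DataFrame(
        {"role": roles, "shift_high1": shift1, "shift_high2": shift2},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return SyntheticCohort(expression, clinical, sample_truth, gene_truth, cfg)


def summarize_cohort(cohort: SyntheticCohort) -> dict:
    """Class sizes, event rates, follow-up and realized planted shifts."""
    cls = cohort.sample_truth["planted_class"]
    clin = cohort.clinical
    n = len(cls)
    summary = {"n_samples": n, "n_genes": cohort.expression.shape[0]}
    for c in ("low", "high1", "high2"):
        members = cls.index[cls == c]
        summary[f"n_{c}"] = len(members)
        summary[f"frac_{c}"] = len(members) / n
        summary[f"events_{c}"] = int(clin.loc[members, "event"].sum())
    summary["n_events"] = int(clin["event"].sum())
    summary["event_fraction"] = float(clin["event"].mean())
    censored = clin.loc[clin["event"] == 0, "time_months"]
    summary["median_followup_censored"] = (
        float(censored.median()) if len(censored) else float("nan")
    )
    # realized mean shift: program-gene group-mean difference vs planted-low
    low_cols = cls.index[cls == "low"]
    for prog, roles, c in (("program1", ("program1_epi", "program1_prolif"), "high1"),
                           ("program2", ("program2",), "high2")):
        genes = cohort.gene_truth.index[cohort.gene_truth["role"].isin(roles)]
        members = cls.index[cls == c]
        if len(genes) and len(members) and len(low_cols):
            sub = cohort.expression.loc[genes]
            summary[f"realized_shift_{prog}"] = float(
                (sub[members].mean(axis=1) - sub[low_cols].mean(axis=1)).mean()
            )
        else:
            summary[f"realized_shift_{prog}"] = float("nan")
    return summary


def config_to_dict(cfg: SyntheticConfig) -> dict:
    return asdict(cfg)
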