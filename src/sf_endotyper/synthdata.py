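"""Synthetic synovial-fluid proteomic cohorts with controllable structure.

The generator emulates the statistical features the downstream pipeline
assumes: a dominant intracellular-contamination factor, spin-status batch
effects, optional planted discrete endotypes, clinical-covariate/protein
links (radiographic-severity latent, a pain latent, a BMI-linked adipokine)
and a blood-staining marker. Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "make_gene_sets",
    "write_cohort",
    "read_cohort",
]

# spillover: fraction of non-intracellular aptamers that also load on the
# contamination factor (at one quarter of the intracellular signal share),
# so the intracellular score is a good but imperfect proxy for PC1
_SPILLOVER_FRAC = 0.05
_SPILLOVER_ATTEN = 0.25

# marginal KL-grade cutpoints on the latent scale (grades 0-4, ~76% advanced)
_KL_CUTS = (-4.1, -2.6, -1.5, 1.7)
_KL_LATENT_WEIGHT = 1.7

_BLOOD_GRADE_P = (0.765, 0.150, 0.050, 0.035)


@dataclass
class CohortConfig:
    """Knobs for :func:`generate_cohort`."""

    n_discovery: int = 708
    n_replication: int = 653
    n_aptamers: int = 600
    n_intracellular: int = 330
    k_endotypes: int = 1
    endotype_separation: float = 0.0
    frac_informative: float = 0.0
    ips_variance_share: float = 0.48
    batch_shift: float = 0.5
    batch_scale: float = 1.5
    frac_unspun: float = 0.15
    clinical_effects: Mapping[str, tuple[int, float]] = field(
        default_factory=lambda: {"advanced_kl": (40, 0.6), "womac_pain": (30, 0.5)}
    )
    adipokine_bmi_corr: float = 0.58
    noise_sd: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_discovery", "n_replication", "n_aptamers", "n_intracellular"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_intracellular >= self.n_aptamers:
            raise ValueError("n_intracellular must be < n_aptamers")
        if not 0.0 <= self.frac_informative <= 1.0:
            raise ValueError("frac_informative must lie in [0, 1]")
        if not 0.0 <= self.ips_variance_share < 1.0:
            raise ValueError("ips_variance_share must lie in [0, 1)")
        if self.k_endotypes < 1:
            raise ValueError("k_endotypes must be >= 1")
        if self.k_endotypes > 1 and self.frac_informative == 0.0:
            raise ValueError(
                "k_endotypes > 1 requires frac_informative > 0 "
                "(endotype effects are unplaceable otherwise)"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 < self.frac_unspun < 1.0:
            raise ValueError("frac_unspun must lie in (0, 1)")


@dataclass
class SyntheticCohort:
    """A generated cohort: abundance + metadata + annotation + sets + truth."""

    abundance: pd.DataFrame  # samples x aptamers, strictly positive
    sample_metadata: pd.DataFrame
    annotation: pd.DataFrame  # aptamer_id, gene, intracellular
    gene_sets: dict[str, list[str]]
    truth: dict
    config: CohortConfig

    def validate(self) -> None:
        if not (self.abundance.to_numpy() > 0).all():
            raise ValueError("abundance must be strictly positive")
        if len(self.sample_metadata) != len(self.abundance):
            raise ValueError("metadata row count must equal abundance row count")
        known = set(self.annotation["aptamer_id"])
        missing = [a for a in self.truth["informative_aptamers"] if a not in known]
        if missing:
            raise ValueError(f"informative aptamers missing from annotation: {missing}")
        labels = np.asarray(self.truth["endotype_labels"])
        if len(np.unique(labels)) != self.config.k_endotypes:
            raise ValueError("truth labels must take exactly k_endotypes values")


def _signal_shares(config: CohortConfig) -> tuple[float, float, int]:
    """Solve the per-aptamer contamination signal share from the target
    variance fraction: mean over aptamers of r^2 with the factor equals
    ips_variance_share (the PC1 share of the standardized matrix)."""
    p, m = config.n_aptamers, config.n_intracellular
    n_spill = int(round(_SPILLOVER_FRAC * (p - m)))
    rho = config.ips_variance_share * p / (m + _SPILLOVER_ATTEN * n_spill)
    if rho >= 0.97:
        raise ValueError(
            "ips_variance_share infeasible for this n_intracellular/n_aptamers "
            f"ratio (required per-aptamer signal share {rho:.3f} >= 0.97)"
        )
    return rho, _SPILLOVER_ATTEN * rho, n_spill


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort under the additive log-abundance model.

    log abundance[i, j] = mu_j + lambda_j * c_i + clinical effects
    + endotype shift + batch term + noise, exponentiated to an RFU-like
    positive scale.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_discovery + config.n_replication
    p = config.n_aptamers
    sd = config.noise_sd

    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    aptamer_ids = [f"APT{j + 1:05d}" for j in range(p)]

    intracellular = np.zeros(p, dtype=bool)
    intracellular[rng.choice(p, size=config.n_intracellular, replace=False)] = True
    extracellular_idx = np.flatnonzero(~intracellular)
    # designated marker aptamers live outside the contamination block
    lep_idx, hba_idx = int(extracellular_idx[0]), int(extracellular_idx[1])

    genes = [f"G{j + 1:05d}" for j in range(p)]
    genes[lep_idx] = "LEP"
    genes[hba_idx] = "HBA1"
    annotation = pd.DataFrame(
        {"aptamer_id": aptamer_ids, "gene": genes, "intracellular": intracellular}
    )

    # ---- metadata -------------------------------------------------------
    dataset = np.array(
        ["Discovery"] * config.n_discovery + ["Replication"] * config.n_replication
    )
    cohort = np.where(
        dataset == "Discovery",
        np.where(rng.random(n) < 0.5, "C1", "C2"),
        np.where(rng.random(n) < 0.5, "C3", "C4"),
    )
    age = rng.normal(64.5, 11.0, n)
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    bmi = np.maximum(rng.normal(30.7, 5.9, n), 15.0)
    spin = np.where(rng.random(n) < config.frac_unspun, "unspun", "spun")
    if (spin == "spun").all():
        spin[0] = "unspun"  # keep both batches represented

    u_kl = rng.standard_normal(n)  # radiographic-severity latent
    eta = _KL_LATENT_WEIGHT * u_kl + rng.logistic(0.0, 1.0, n)
    kl_grade = (eta[:, None] > np.asarray(_KL_CUTS)[None, :]).sum(axis=1)
    w_pain = rng.standard_normal(n)
    womac = np.clip(44.9 + 21.1 * w_pain, 0.0, 100.0)
    blood = rng.choice([1, 2, 3, 4], size=n, p=_BLOOD_GRADE_P)

    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "cohort": cohort,
            "dataset": dataset,
            "spin_status": spin,
            "kl_grade": kl_grade,
            "womac_pain": womac,
            "blood_staining": blood,
        }
    ).set_index("sample_id", drop=False)

    # ---- log-abundance model -------------------------------------------
    rho_intra, rho_spill, n_spill = _signal_shares(config)
    lam = np.zeros(p)
    lam[intracellular] = sd * np.sqrt(rho_intra / (1.0 - rho_intra))
    spill_pool = np.array(
        [j for j in extracellular_idx if j not in (lep_idx, hba_idx)]
    )
    spill_idx = rng.choice(spill_pool, size=min(n_spill, len(spill_pool)), replace=False)
    lam[spill_idx] = sd * np.sqrt(rho_spill / (1.0 - rho_spill))

    contamination = rng.standard_normal(n)
    mu = rng.normal(7.0, 0.8, p)
    log_x = mu[None, :] + np.outer(contamination, lam)

    reserved = {lep_idx, hba_idx}
    effects: dict[str, dict[str, float]] = {}
    latents = {"advanced_kl": u_kl, "womac_pain": w_pain}
    for outcome, (n_affected, beta) in config.clinical_effects.items():
        if outcome not in latents:
            raise ValueError(f"unknown clinical outcome {outcome!r}")
        pool = np.array([j for j in range(p) if j not in reserved])
        chosen = rng.choice(pool, size=min(n_affected, len(pool)), replace=False)
        signs = rng.choice([-1.0, 1.0], size=len(chosen))
        log_x[:, chosen] += np.outer(latents[outcome], beta * sd * signs)
        effects[outcome] = {
            aptamer_ids[j]: float(beta * s) for j, s in zip(chosen, signs)
        }

    # adipokine: exact target correlation with BMI by construction
    r = config.adipokine_bmi_corr
    bmi_z = (bmi - bmi.mean()) / bmi.std(ddof=1)
    log_x[:, lep_idx] = mu[lep_idx] + sd * r / np.sqrt(1.0 - r**2) * bmi_z
    # blood-staining marker: additive shift per grade above 1
    log_x[:, hba_idx] += 0.8 * sd * (blood - 1)

    if config.k_endotypes > 1:
        labels = rng.permutation(np.arange(n) % config.k_endotypes)
        n_inf = int(round(config.frac_informative * p))
        if n_inf < 1:
            raise ValueError("frac_informative too small: no informative aptamers")
        pool = np.array([j for j in range(p) if j not in reserved])
        inf_idx = np.sort(rng.choice(pool, size=min(n_inf, len(pool)), replace=False))
        signs = rng.choice([-1.0, 1.0], size=len(inf_idx))
        centered = labels - (config.k_endotypes - 1) / 2.0
        log_x[:, inf_idx] += np.outer(
            centered, config.endotype_separation * sd * signs
        )
        informative = [aptamer_ids[j] for j in inf_idx]
    else:
        labels = np.zeros(n, dtype=int)
        informative = []

    unspun = spin == "unspun"
    gamma = rng.normal(config.batch_shift, 0.05, p)
    log_x[unspun] += gamma[None, :]
    eps = rng.standard_normal((n, p)) * sd
    eps[unspun] *= np.sqrt(config.batch_scale)
    log_x += eps

    abundance = pd.DataFrame(np.exp(log_x), index=sample_ids, columns=aptamer_ids)
    abundance.index.name = "sample_id"

    truth = {
        "endotype_labels": labels,
        "contamination": contamination,
        "informative_aptamers": informative,
        "effects": effects,
        "latents": latents,
        "adipokine_aptamer": aptamer_ids[lep_idx],
        "haemoglobin_aptamer": aptamer_ids[hba_idx],
    }

    if informative:
        planted_genes = [genes[aptamer_ids.index(a)] for a in informative]
    else:
        planted_genes = sorted(
            genes[aptamer_ids.index(a)] for a in effects.get("advanced_kl", {})
        )
    gene_sets = make_gene_sets(
        annotation, planted_genes, rng=np.random.default_rng(config.seed + 1)
    )

    cohort_obj = SyntheticCohort(abundance, metadata, annotation, gene_sets, truth, config)
    cohort_obj.validate()
    return cohort_obj


def make_gene_sets(
    annotation: pd.DataFrame,
    planted_genes: list[str],
    n_decoys: int = 10,
    decoy_size: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, list[str]]:
    """Planted-enriched set plus size-matched uniform decoy sets.

    The ``PLANTED`` set is the genes carrying true effects; decoys are drawn
    uniformly from the annotation, so under the null they are exchangeable
    with any random gene set of the same size.
    """
    if annotation.empty:
        raise ValueError("annotation is empty")
    if not planted_genes:
        raise ValueError("cannot plant an enriched set with zero informative genes")
    rng = rng if rng is not None else np.random.default_rng(0)
    universe = list(annotation["gene"])
    if len(planted_genes) > len(universe):
        raise ValueError("planted set larger than gene universe")
    size = decoy_size if decoy_size is not None else len(planted_genes)
    if size > len(universe):
        raise ValueError(f"decoy size {size} exceeds number of genes {len(universe)}")
    sets = {"PLANTED": sorted(planted_genes)}
    for d in range(n_decoys):
        members = rng.choice(universe, size=size, replace=False)
        sets[f"DECOY_{d + 1:02d}"] = sorted(members)
    return sets


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Serialize a cohort to plain-text files (TSV/GMT/JSON); lossless
    round trip via ``repr`` float formatting."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if cohort.abundance.index.duplicated().any():
        dups = cohort.abundance.index[cohort.abundance.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")

    paths = {
        "abundance": directory / "abundance.tsv",
        "metadata": directory / "metadata.tsv",
        "annotation": directory / "annotation.tsv",
        "gene_sets": directory / "gene_sets.gmt",
        "truth": directory / "truth.json",
    }
    cohort.abundance.to_csv(paths["abundance"], sep="\t")
    cohort.sample_metadata.to_csv(paths["metadata"], sep="\t", index=False)
    cohort.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    with open(paths["gene_sets"], "w") as fh:
        for name, members in cohort.gene_sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")
    truth_json = {
        "endotype_labels": np.asarray(cohort.truth["endotype_labels"]).tolist(),
        "contamination": np.asarray(cohort.truth["contamination"]).tolist(),
        "informative_aptamers": list(cohort.truth["informative_aptamers"]),
        "effects": cohort.truth["effects"],
        "adipokine_aptamer": cohort.truth["adipokine_aptamer"],
        "haemoglobin_aptamer": cohort.truth["haemoglobin_aptamer"],
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_json, fh, indent=1)
    return paths


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort` (truth partially
    restored; config not serialized)."""
    directory = Path(directory)
    abundance = pd.read_csv(directory / "abundance.tsv", sep="\t", index_col=0)
    if abundance.index.duplicated().any():
        raise ValueError("duplicate sample ids in abundance file")
    metadata = pd.read_csv(directory / "metadata.tsv", sep="\t").set_index(
        "sample_id", drop=False
    )
    annotation = pd.read_csv(directory / "annotation.tsv", sep="\t")
    gene_sets: dict[str, list[str]] = {}
    with open(directory / "gene_sets.gmt") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                gene_sets[parts[0]] = parts[2:]
    with open(directory / "truth.json") as fh:
        truth = json.load(fh)
    truth["endotype_labels"] = np.asarray(truth["endotype_labels"])
    truth["contamination"] = np.asarray(truth["contamination"])
    k = max(1, len(np.unique(truth["endotype_labels"])))
    cfg = CohortConfig(
        n_discovery=int((metadata["dataset"] == "Discovery").sum()),
        n_replication=int((metadata["dataset"] == "Replication").sum()),
        n_aptamers=abundance.shape[1],
        n_intracellular=int(annotation["intracellular"].sum()),
        k_endotypes=k,
        frac_informative=len(truth["informative_aptamers"]) / abundance.shape[1]
        if k > 1
        else 0.0,
    )
    return SyntheticCohort(abundance, metadata, annotation, gene_sets, truth, cfg)
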