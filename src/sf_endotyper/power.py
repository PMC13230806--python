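"""Simulation-based operating characteristics of the cluster-detection
procedure: detection probability versus sample size, endotype count,
separation and informative fraction."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import endotype, preprocess, synthdata

__all__ = ["PowerGrid", "PowerResult", "estimate_power", "power_curve", "run_detection"]


@dataclass
class PowerGrid:
    """Scenario tuples (n, k_endotypes, separation, frac_informative)."""

    scenarios: list[tuple[int, int, float, float]]
    n_reps: int = 50
    seed: int = 0
    threshold: float = endotype.DEFAULT_THRESHOLD
    n_aptamers: int = 300  # reduced aptamer count for desk-scale runtime
    ips_regress: bool = True
    k_max: int = 9
    ips_variance_share: float = 0.48

    def validate(self) -> None:
        if self.n_reps < 20:
            raise ValueError("n_reps must be >= 20")
        if not self.scenarios:
            raise ValueError("scenarios must be non-empty")
        for n, k, sep, frac in self.scenarios:
            if k >= n:
                raise ValueError(f"scenario with k_endotypes={k} >= n={n}")


@dataclass
class PowerResult:
    table: pd.DataFrame
    grid: PowerGrid


def run_detection(
    cohort: synthdata.SyntheticCohort,
    ips_regress: bool = True,
    k_max: int = 9,
    threshold: float = endotype.DEFAULT_THRESHOLD,
    seed: int | None = None,
    variance_target: float = 0.80,
) -> tuple[endotype.ClusterDecision, endotype.ClusterScan, endotype.ReducedSpace]:
    """Full preprocess -> reduce -> scan -> decide path on one cohort."""
    mat = preprocess.AbundanceMatrix(cohort.abundance)
    mat = preprocess.log_transform(mat)
    mat = preprocess.median_normalize(mat)
    mat = preprocess.batch_adjust_eb(mat, cohort.sample_metadata["spin_status"])
    if ips_regress:
        ips = preprocess.compute_ips(mat, cohort.annotation)
        mat = preprocess.residualize(mat, ips.scores.to_numpy())
    space = endotype.pca_reduce(mat, variance_target)
    scan = endotype.kmeans_scan(space, k_max=k_max, seed=seed)
    endotype.f_of_k(scan)
    decision = endotype.decide_from_scan(scan, threshold)
    return decision, scan, space


def estimate_power(grid: PowerGrid) -> PowerResult:
    """Monte-Carlo detection proportion per scenario, with MC standard
    error and mean chosen K (the f-statistic argmin) among detections."""
    grid.validate()
    rows = []
    for idx, (n, k, sep, frac) in enumerate(grid.scenarios):
        detected = 0
        chosen: list[int] = []
        for rep in range(grid.n_reps):
            sub = np.random.SeedSequence([grid.seed, idx, rep])
            cohort_seed = int(sub.generate_state(1)[0] % (2**31))
            config = synthdata.CohortConfig(
                n_discovery=max(n // 2, 2),
                n_replication=max(n - n // 2, 2),
                n_aptamers=grid.n_aptamers,
                n_intracellular=max(int(0.55 * grid.n_aptamers), 1),
                k_endotypes=k,
                endotype_separation=sep,
                frac_informative=frac if k > 1 else 0.0,
                ips_variance_share=grid.ips_variance_share,
                seed=cohort_seed,
            )
            cohort = synthdata.generate_cohort(config)
            decision, _, _ = run_detection(
                cohort,
                ips_regress=grid.ips_regress,
                k_max=grid.k_max,
                threshold=grid.threshold,
                seed=cohort_seed + 1,
            )
            if decision.clustered:
                detected += 1
                chosen.append(decision.argmin_k)
        prop = detected / grid.n_reps
        rows.append(
            {
                "n": n,
                "k_endotypes": k,
                "separation": sep,
                "frac_informative": frac,
                "detection_proportion": prop,
                "mc_se": float(np.sqrt(prop * (1 - prop) / grid.n_reps)),
                "mean_chosen_k": float(np.mean(chosen)) if chosen else float("nan"),
                "n_reps": grid.n_reps,
            }
        )
    return PowerResult(pd.DataFrame(rows), grid)


def power_curve(result: PowerResult, plot_path=None) -> pd.DataFrame:
    """Detection proportion versus the single varied scenario factor."""
    table = result.table
    factors = ["n", "k_endotypes", "separation", "frac_informative"]
    varied = [f for f in factors if table[f].nunique() > 1]
    if len(table) < 2:
        raise ValueError("need at least 2 scenarios for a curve")
    if len(varied) != 1:
        raise ValueError(
            f"exactly one factor must vary across scenarios, found {varied}"
        )
    factor = varied[0]
    curve = table.sort_values(factor).reset_index(drop=True)
    props = curve["detection_proportion"].to_numpy()
    ses = curve["mc_se"].to_numpy()
    tol = 2.0 * np.sqrt(ses[1:] ** 2 + ses[:-1] ** 2)
    curve.attrs["monotone_within_mc_error"] = bool(
        np.all(np.diff(props) >= -tol)
    )
    curve.attrs["factor"] = factor
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.errorbar(
            curve[factor], props, yerr=2 * ses, marker="o", capsize=3
        )
        ax.set_xlabel(factor)
        ax.set_ylabel("detection proportion")
        ax.set_ylim(-0.02, 1.02)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=100)
        plt.close(fig)
    return curve
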