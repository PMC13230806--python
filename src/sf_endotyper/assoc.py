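"""Per-protein association scan with covariate adjustment, BH-FDR,
replication calls, interaction tests, stratified reruns and
duplicate-aptamer handling.

Each aptamer is modelled separately with the clinical feature as the
dependent variable and the standardized log abundance as the independent
variable: linear for continuous outcomes, logistic for binary, proportional
odds for ordered categorical. Effects are therefore per-SD of log
abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "OutcomeSpec",
    "fit_protein_association",
    "bh_adjust",
    "call_replication",
    "test_interaction",
    "select_best_aptamer",
    "run_stratified",
    "derive_outcome",
]

_FAMILIES = ("continuous", "binary", "ordinal")

# built-in derivation rules for outcomes not stored directly as columns
_DERIVATIONS = {
    "advanced_kl": lambda md: (md["kl_grade"] >= 3).astype(float),
    "obese": lambda md: (md["bmi"] >= 30.0).astype(float),
}


@dataclass(frozen=True)
class OutcomeSpec:
    """What to regress, against what, and how."""

    name: str
    family: str
    outcome: str | None = None  # metadata column; None -> derivation rule by name
    covariates: tuple[str, ...] = ("age", "sex")
    cohort_adjust: str = "none"  # none | fixed | random
    extra_covariates: tuple[str, ...] = ()
    min_n: int = 30

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if self.cohort_adjust not in ("none", "fixed", "random"):
            raise ValueError("cohort_adjust must be none|fixed|random")


def derive_outcome(metadata: pd.DataFrame, spec: OutcomeSpec) -> pd.Series:
    if spec.outcome is not None:
        if spec.outcome not in metadata.columns:
            raise KeyError(f"outcome column {spec.outcome!r} not in metadata")
        return metadata[spec.outcome]
    if spec.name in _DERIVATIONS:
        return _DERIVATIONS[spec.name](metadata)
    if spec.name in metadata.columns:
        return metadata[spec.name]
    raise KeyError(f"no outcome column or derivation rule for {spec.name!r}")


def _encode_covariates(metadata: pd.DataFrame, spec: OutcomeSpec) -> pd.DataFrame:
    cols = {}
    for cov in tuple(spec.covariates) + tuple(spec.extra_covariates):
        if cov not in metadata.columns:
            raise KeyError(f"covariate {cov!r} not in metadata")
        col = metadata[cov]
        if col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols[c] = dummies[c]
        else:
            cols[cov] = col.astype(float)
    if spec.cohort_adjust == "fixed":
        dummies = pd.get_dummies(
            metadata["cohort"], prefix="cohort", drop_first=True, dtype=float
        )
        for c in dummies.columns:
            cols[c] = dummies[c]
    return pd.DataFrame(cols, index=metadata.index)


def _fit_one(
    y: np.ndarray,
    design: pd.DataFrame,
    family: str,
    groups: np.ndarray | None,
    term: str = "protein",
) -> tuple[float, float, float, bool]:
    """Fit one model; return (effect, se, p, flagged)."""
    flagged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if family == "continuous":
                if groups is not None:
                    model = sm.MixedLM(y, sm.add_constant(design), groups=groups)
                    res = model.fit(reml=True)
                else:
                    res = sm.OLS(y, sm.add_constant(design)).fit()
                return (
                    float(res.params[term]),
                    float(res.bse[term]),
                    float(res.pvalues[term]),
                    False,
                )
            if family == "binary":
                res = sm.Logit(y, sm.add_constant(design)).fit(disp=0, maxiter=100)
                eff, se = float(res.params[term]), float(res.bse[term])
                if not res.mle_retvals.get("converged", True) or abs(eff) > 15 or se > 50:
                    return eff, se, float("nan"), True
                return eff, se, float(res.pvalues[term]), False
            # ordinal: proportional odds with ordered integer levels
            design = design.reset_index(drop=True)
            y_cat = pd.Series(y).astype(
                pd.CategoricalDtype(categories=np.unique(y), ordered=True)
            )
            res = OrderedModel(y_cat, design, distr="logit").fit(
                method="bfgs", disp=0, maxiter=200
            )
            return (
                float(res.params[term]),
                float(res.bse[term]),
                float(res.pvalues[term]),
                False,
            )
        except (PerfectSeparationError, np.linalg.LinAlgError):
            return float("nan"), float("nan"), float("nan"), True


def fit_protein_association(
    matrix, metadata: pd.DataFrame, spec: OutcomeSpec, annotation: pd.DataFrame | None = None
) -> pd.DataFrame:
    """One association record per aptamer (complete-case per aptamer).

    ``matrix`` must be standardized per protein within the analysis dataset
    so effects read as change per SD of log abundance.
    """
    data = matrix.data if hasattr(matrix, "data") else pd.DataFrame(matrix)
    metadata = metadata.loc[data.index]
    y_all = derive_outcome(metadata, spec).astype(float)
    covars = _encode_covariates(metadata, spec)
    gene_map = (
        dict(zip(annotation["aptamer_id"], annotation["gene"]))
        if annotation is not None
        else {}
    )

    base_mask = y_all.notna().to_numpy()
    for c in covars.columns:
        base_mask &= covars[c].notna().to_numpy()
    if spec.family == "binary" and len(np.unique(y_all[base_mask].dropna())) < 2:
        raise ValueError(f"outcome {spec.name!r} is constant")
    if spec.family == "ordinal" and len(np.unique(y_all[base_mask].dropna())) < 3:
        raise ValueError(f"ordinal outcome {spec.name!r} has < 3 levels")
    if base_mask.sum() < spec.min_n:
        raise ValueError(
            f"only {int(base_mask.sum())} usable samples (< min_n={spec.min_n})"
        )
    groups_all = (
        metadata["cohort"].to_numpy() if spec.cohort_adjust == "random" else None
    )

    records = []
    for aptamer in data.columns:
        x = data[aptamer].to_numpy(dtype=float)
        mask = base_mask & np.isfinite(x)
        design = covars.loc[mask].copy()
        design.insert(0, "protein", x[mask])
        y = y_all.to_numpy(dtype=float)[mask]
        groups = groups_all[mask] if groups_all is not None else None
        eff, se, p, flagged = _fit_one(y, design, spec.family, groups)
        records.append(
            {
                "aptamer_id": aptamer,
                "gene": gene_map.get(aptamer, aptamer),
                "effect": eff,
                "se": se,
                "p": p,
                "n": int(mask.sum()),
                "direction": int(np.sign(eff)) if np.isfinite(eff) else 0,
                "flagged": flagged,
            }
        )
    out = pd.DataFrame.from_records(records)
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out[
        ["aptamer_id", "gene", "effect", "se", "p", "padj", "n", "direction", "flagged"]
    ]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs propagate)."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[mask] = res
    return out


def call_replication(
    discovery: pd.DataFrame, replication: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Replicated iff padj <= alpha in both datasets with the same
    direction of effect."""
    common = discovery.merge(
        replication, on="aptamer_id", suffixes=("_disc", "_rep"), how="inner"
    )
    if common.empty:
        raise ValueError("no overlapping aptamers between datasets")
    sig_d = common["padj_disc"] <= alpha
    sig_r = common["padj_rep"] <= alpha
    same_dir = (
        common["direction_disc"] == common["direction_rep"]
    ) & (common["direction_disc"] != 0)
    common["replicated"] = (sig_d & sig_r & same_dir).to_numpy()
    common.attrs["summary"] = {
        "replicated": int(common["replicated"].sum()),
        "discovery_only": int((sig_d & ~common["replicated"]).sum()),
        "replication_only": int((sig_r & ~common["replicated"]).sum()),
    }
    return common


def test_interaction(
    matrix, metadata: pd.DataFrame, spec: OutcomeSpec, modifier: str
) -> pd.DataFrame:
    """Protein-by-modifier interaction per aptamer (modifier dichotomous),
    with main effects included; BH across aptamers."""
    data = matrix.data if hasattr(matrix, "data") else pd.DataFrame(matrix)
    metadata = metadata.loc[data.index]
    if modifier in _DERIVATIONS:
        mod = _DERIVATIONS[modifier](metadata)
    elif modifier in metadata.columns:
        col = metadata[modifier]
        mod = (
            (col == sorted(col.dropna().unique())[-1]).astype(float)
            if col.dtype == object
            else col.astype(float)
        )
    else:
        raise KeyError(f"modifier {modifier!r} not available")
    mod = mod.astype(float)
    vals = mod.dropna().unique()
    if len(vals) < 2:
        raise ValueError("modifier is constant")
    if len(vals) > 2:
        raise ValueError("modifier must be dichotomous")

    y_all = derive_outcome(metadata, spec).astype(float)
    covars = _encode_covariates(metadata, spec)
    base_mask = y_all.notna().to_numpy() & mod.notna().to_numpy()
    for c in covars.columns:
        base_mask &= covars[c].notna().to_numpy()

    records = []
    for aptamer in data.columns:
        x = data[aptamer].to_numpy(dtype=float)
        mask = base_mask & np.isfinite(x)
        design = covars.loc[mask].copy()
        design.insert(0, "protein", x[mask])
        design.insert(1, "modifier", mod.to_numpy()[mask])
        design.insert(2, "protein_x_modifier", x[mask] * mod.to_numpy()[mask])
        y = y_all.to_numpy(dtype=float)[mask]
        eff, se, p, flagged = _fit_one(
            y, design, spec.family, None, term="protein_x_modifier"
        )
        records.append(
            {
                "aptamer_id": aptamer,
                "interaction": eff,
                "se": se,
                "p": p,
                "n": int(mask.sum()),
                "flagged": flagged,
            }
        )
    out = pd.DataFrame.from_records(records)
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out


def select_best_aptamer(results: pd.DataFrame) -> pd.DataFrame:
    """Keep one record per gene: smallest padj, ties by smallest p, then
    lexicographic aptamer id."""
    if "gene" not in results.columns:
        raise ValueError("gene symbols must be attached")
    ordered = results.sort_values(
        ["gene", "padj", "p", "aptamer_id"], kind="mergesort", na_position="last"
    )
    return ordered.drop_duplicates("gene", keep="first").reset_index(drop=True)


def _parse_rule(rule: str):
    for op in (">=", "<=", ">", "<", "=="):
        if op in rule:
            col, val = rule.split(op, 1)
            col, val = col.strip(), val.strip()
            try:
                val = float(val)
            except ValueError:
                pass
            return col, op, val
    raise ValueError(f"cannot parse stratum rule {rule!r}")


def run_stratified(
    matrix, metadata: pd.DataFrame, rule: str, spec: OutcomeSpec
) -> dict:
    """Rerun an association analysis within each stratum of a rule like
    ``"bmi>=30"`` or ``"sex==F"``; returns per-stratum results plus the
    cross-stratum correlation of effects."""
    data = matrix.data if hasattr(matrix, "data") else pd.DataFrame(matrix)
    metadata = metadata.loc[data.index]
    col, op, val = _parse_rule(rule)
    if col not in metadata.columns:
        raise KeyError(f"stratum column {col!r} not in metadata")
    series = metadata[col]
    ops = {
        ">=": series >= val,
        "<=": series <= val,
        ">": series > val,
        "<": series < val,
        "==": series == val,
    }
    mask = ops[op]
    groups = {f"{rule}": mask, f"not({rule})": ~mask}
    if any(m.sum() == 0 for m in groups.values()):
        raise ValueError(f"rule {rule!r} yields an empty stratum")

    results = {}
    for name, m in groups.items():
        sub_md = metadata.loc[m]
        sub_spec = spec
        # collinearity guard: drop covariates constant within the stratum
        keep = tuple(
            c for c in spec.covariates if sub_md[c].nunique(dropna=True) > 1
        )
        if keep != tuple(spec.covariates):
            sub_spec = replace(spec, covariates=keep)
        sub = data.loc[m]
        # re-standardize within stratum so effects stay per-SD
        sd = sub.std(ddof=1)
        sub = (sub - sub.mean()) / sd.replace(0.0, np.nan)
        results[name] = fit_protein_association(sub, sub_md, sub_spec)

    names = list(results)
    merged = results[names[0]].merge(
        results[names[1]], on="aptamer_id", suffixes=("_a", "_b")
    )
    finite = merged[["effect_a", "effect_b"]].dropna()
    corr = (
        float(np.corrcoef(finite["effect_a"], finite["effect_b"])[0, 1])
        if len(finite) > 2
        else float("nan")
    )
    return {"strata": results, "effect_correlation": corr}
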