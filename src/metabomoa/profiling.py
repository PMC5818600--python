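"""Per-treatment metabolic profiles and study-level summaries.

The unit of downstream analysis is the metabolic profile: for one
treatment/dose against its matched vehicle controls, the per-metabolite
Welch t statistic, two-sided p value, and ratio of group medians on the
linear (ratio) scale.  Controls are matched within work package — every
experiment runs its own vehicle controls, so treated samples are only ever
compared against controls measured alongside them.

The Welch statistic is the pipeline's core quantity and is computed here
explicitly:

    t = (mean_T - mean_C) / sqrt(s_T^2/n_T + s_C^2/n_C)

with Welch–Satterthwaite degrees of freedom; p values come from the central
t distribution.  Metabolites for which the statistic is undefined (zero
variance in both groups with equal means, or fewer than two observations in
a group) are flagged degenerate and carried with NaN statistics, never
silently dropped or poisoned into downstream correlations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import AbundanceMatrix, ValidationError


@dataclass
class MetabolicProfile:
    """Per-metabolite (t, p, median ratio) for one treatment/dose vs control.

    ``data`` is indexed by metabolite_id with columns
    ``t_value, p_value, median_ratio, significant, direction, degenerate``.
    """

    treatment: str
    dose: str
    compartment: str
    alpha: float
    data: pd.DataFrame
    n_treated: int = 0
    n_control: int = 0

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.treatment, self.dose, self.compartment)

    def t_values(self, drop_degenerate: bool = True) -> pd.Series:
        d = self.data
        if drop_degenerate:
            d = d[~d["degenerate"]]
        return d["t_value"]

    def significant_set(self) -> set[tuple[str, str]]:
        sig = self.data[self.data["significant"]]
        return set(zip(sig.index, sig["direction"]))


def welch_profile(
    m: AbundanceMatrix,
    treatment: str,
    dose: str,
    alpha: float = 0.05,
    pool_controls_across_packages: bool = False,
) -> MetabolicProfile:
    """Welch-test every metabolite for one treated group against its controls.

    Controls are the vehicle controls of the work packages in which the
    treated group was run (set ``pool_controls_across_packages`` to use all
    controls in the study).
    """
    if m.scale != "log10":
        raise ValidationError(f"welch_profile expects scale 'log10', got {m.scale!r}")
    s = m.samples
    treated_mask = (s["role"] == "treated") & (s["treatment"] == treatment) & (s["dose"] == dose)
    treated_ids = list(s.index[treated_mask])
    if len(treated_ids) < 2:
        raise ValidationError(
            f"treated group {treatment}/{dose} has {len(treated_ids)} samples (<2)"
        )
    if pool_controls_across_packages:
        control_mask = s["role"] == "vehicle_control"
    else:
        wps = set(s.loc[treated_ids, "work_package"])
        control_mask = (s["role"] == "vehicle_control") & s["work_package"].isin(wps)
    control_ids = list(s.index[control_mask])
    if len(control_ids) < 2:
        raise ValidationError(
            f"matched vehicle-control group for {treatment}/{dose} has "
            f"{len(control_ids)} samples (<2)"
        )

    xt = m.values.loc[treated_ids].to_numpy(dtype=float)
    xc = m.values.loc[control_ids].to_numpy(dtype=float)

    def _moments(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n = np.sum(~np.isnan(x), axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(x, axis=0)
            var = np.nanvar(x, axis=0, ddof=1)
        return n, mean, var

    n1, m1, v1 = _moments(xt)
    n0, m0, v0 = _moments(xc)

    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = v1 / n1 + v0 / n0
        t = (m1 - m0) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1))

    degenerate = (n1 < 2) | (n0 < 2) | ((se2 == 0) & (m1 == m0)) | np.isnan(se2)
    exact = (se2 == 0) & (m1 != m0) & ~degenerate  # separated point masses
    p = np.full_like(t, np.nan)
    ok = ~degenerate & ~exact
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    t = np.where(exact, np.where(m1 > m0, np.inf, -np.inf), t)
    p[exact] = 0.0
    t[degenerate] = np.nan

    # group medians on the linear ratio scale
    lin_t = np.power(10.0, xt)
    lin_c = np.power(10.0, xc)
    with np.errstate(invalid="ignore"):
        med_ratio = np.nanmedian(lin_t, axis=0) / np.nanmedian(lin_c, axis=0)

    significant = ~degenerate & (p < alpha)
    direction = np.where(
        significant, np.where(med_ratio > 1.0, "up", "down"), "none"
    )
    data = pd.DataFrame(
        {
            "t_value": t,
            "p_value": p,
            "median_ratio": med_ratio,
            "significant": significant,
            "direction": direction,
            "degenerate": degenerate,
        },
        index=m.values.columns,
    )
    data.index.name = "metabolite_id"
    return MetabolicProfile(
        treatment=treatment,
        dose=dose,
        compartment=str(s.loc[treated_ids[0], "compartment"]),
        alpha=alpha,
        data=data,
        n_treated=len(treated_ids),
        n_control=len(control_ids),
    )


def profile_all(
    m: AbundanceMatrix, alpha: float = 0.05, doses: tuple[str, ...] = ("LD", "HD")
) -> list[MetabolicProfile]:
    """Profile every treated (treatment, dose) group present in the study."""
    s = m.samples
    groups = (
        s[s["role"] == "treated"][["treatment", "dose"]]
        .drop_duplicates()
        .itertuples(index=False)
    )
    return [
        welch_profile(m, g.treatment, g.dose, alpha=alpha)
        for g in groups
        if g.dose in doses
    ]


def count_changed(p: MetabolicProfile) -> int:
    """Number of significantly changed metabolites in a profile."""
    return int(p.data["significant"].sum())


@dataclass
class DoseSelection:
    substance: str
    tested_concentrations: list[tuple[float, float]]  # (conc, protein % of control)
    HD: float
    LD: float


def select_doses(
    substance: str, conc_protein_table: list[tuple[float, float]]
) -> DoseSelection:
    """Range-finder rule: HD is the largest tested concentration keeping total
    protein at >=80% of control; LD is one third of HD (not snapped to a
    tested concentration)."""
    table = [(float(c), float(p)) for c, p in conc_protein_table]
    if len(table) < 2:
        raise ValidationError("need at least 2 tested concentrations")
    eligible = [c for c, pct in table if pct >= 80.0]
    if not eligible:
        raise ValidationError(
            f"{substance}: no tested concentration keeps protein >=80% of "
            "control; repeat the range finder with lower concentrations"
        )
    hd = max(eligible)
    return DoseSelection(
        substance=substance, tested_concentrations=table, HD=hd, LD=hd / 3.0
    )


# -- factorial linear models -------------------------------------------------


@dataclass
class FactorialFit:
    """Per-metabolite OLS on the categorical study design.

    Fitted on treated samples with the factors substance, dose and work
    package (those with >=2 levels) and all their interactions; aliased
    terms are dropped before fitting and listed in ``aliased``.
    """

    formula: str
    anova: pd.DataFrame  # metabolite_id, term, F, p, df
    coefficients: pd.DataFrame  # metabolite_id, term, estimate
    aliased: list[str] = field(default_factory=list)


def _candidate_terms(factors: list[str]) -> list[str]:
    terms = []
    for r in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, r):
            terms.append(":".join(f"C({f})" for f in combo))
    return terms


def fit_factorial(
    m: AbundanceMatrix, metabolites: list[str] | None = None
) -> FactorialFit:
    """Fit ``value ~ substance * dose * work_package`` per metabolite.

    Uses ordinary least squares with type-II F tests.  Rank-deficient
    designs are handled by dropping aliased (highest-order first) terms and
    reporting them.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from patsy import dmatrix

    if m.scale != "log10":
        raise ValidationError(f"fit_factorial expects scale 'log10', got {m.scale!r}")
    s = m.samples
    treated = s[s["role"] == "treated"]
    if len(treated) < 3:
        raise ValidationError("factorial fit needs at least 3 treated samples")
    frame = pd.DataFrame(
        {
            "substance": treated["treatment"].to_numpy(),
            # LD as the reference level: dose effects read as HD-above-LD
            "dose": pd.Categorical(
                treated["dose"].to_numpy(),
                categories=[d for d in ("LD", "HD") if d in set(treated["dose"])],
            ),
            "work_package": treated["work_package"].to_numpy(),
        },
        index=treated.index,
    )
    factors = [f for f in ("substance", "dose", "work_package") if frame[f].nunique() >= 2]
    if not factors:
        raise ValidationError("no factor has >=2 levels; nothing to fit")
    terms = _candidate_terms(factors)
    aliased: list[str] = []
    # drop aliased terms, highest interaction order first, until full rank
    while True:
        rhs = " + ".join(terms)
        X = np.asarray(dmatrix(rhs, frame, return_type="dataframe"))
        if np.linalg.matrix_rank(X) == X.shape[1] and X.shape[0] > X.shape[1]:
            break
        order = lambda t: t.count(":")
        drop = max(terms, key=lambda t: (order(t), t))
        aliased.append(drop)
        terms = [t for t in terms if t != drop]
        if not terms:
            raise ValidationError("design fully aliased; no estimable terms")
    formula_rhs = " + ".join(terms)

    mids = metabolites if metabolites is not None else list(m.values.columns)
    anova_rows, coef_rows = [], []
    for mid in mids:
        frame["value"] = m.values.loc[treated.index, mid].to_numpy(dtype=float)
        fit = smf.ols(f"value ~ {formula_rhs}", data=frame.dropna(subset=["value"])).fit()
        if fit.df_resid <= 0:
            raise ValidationError(f"{mid}: no residual degrees of freedom")
        tab = sm.stats.anova_lm(fit, typ=2)
        for term, row in tab.iterrows():
            if term == "Residual":
                continue
            anova_rows.append(
                {"metabolite_id": mid, "term": term, "F": row["F"], "p": row["PR(>F)"], "df": row["df"]}
            )
        for term, est in fit.params.items():
            coef_rows.append({"metabolite_id": mid, "term": term, "estimate": est})
    return FactorialFit(
        formula=f"value ~ {formula_rhs}",
        anova=pd.DataFrame(anova_rows),
        coefficients=pd.DataFrame(coef_rows),
        aliased=aliased,
    )


# -- profile interchange (flat-file profile store) ---------------------------

_PROFILE_COLUMNS = [
    "treatment",
    "dose",
    "compartment",
    "alpha",
    "metabolite_id",
    "t_value",
    "p_value",
    "median_ratio",
    "significant",
    "direction",
    "degenerate",
]


def write_profiles(profiles: list[MetabolicProfile], path) -> None:
    """Write profiles as one long-format TSV (the flat-file profile store)."""
    frames = []
    for p in profiles:
        d = p.data.reset_index()
        d.insert(0, "treatment", p.treatment)
        d.insert(1, "dose", p.dose)
        d.insert(2, "compartment", p.compartment)
        d.insert(3, "alpha", p.alpha)
        frames.append(d[_PROFILE_COLUMNS])
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_profiles(path) -> list[MetabolicProfile]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    out = []
    for (treatment, dose, compartment, alpha), sub in df.groupby(
        ["treatment", "dose", "compartment", "alpha"], sort=False
    ):
        data = sub.set_index("metabolite_id")[
            ["t_value", "p_value", "median_ratio", "significant", "direction", "degenerate"]
        ].copy()
        data["significant"] = data["significant"].astype(bool)
        data["degenerate"] = data["degenerate"].astype(bool)
        out.append(
            MetabolicProfile(
                treatment=treatment,
                dose=dose,
                compartment=compartment,
                alpha=float(alpha),
                data=data,
            )
        )
    return out
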