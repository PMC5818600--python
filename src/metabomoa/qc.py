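"""Reproducibility monitoring (RSD) and PCA views of a study.

Variability on the multiplicative scale is summarized per work package as a
relative standard deviation back-transformed from the log10-scale sample
standard deviation:

    RSD = 1 - 10**(-sd_log)

Vehicle controls carry biological plus technical spread (total), pool
replicates technical only; the biological component is recovered by
subtracting the technical from the total *variance* on the log scale,
clamping small-sample negatives to zero (and counting the clamps):

    RSD_bio = 1 - 10**(-sqrt(max(sd_total^2 - sd_tech^2, 0)))

PCA operates on the log10 matrix, centered and scaled to unit variance per
metabolite so that no single high-variance metabolite dominates; it is
computed by a full (non-randomized) SVD with a fixed sign convention — the
largest-magnitude loading of each component is positive — so scores are
bit-reproducible across runs and metabolite orderings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import AbundanceMatrix, ValidationError


def rsd_from_sdlog(sd_log: float | np.ndarray) -> float | np.ndarray:
    """Back-transform a log10-scale standard deviation to a linear RSD."""
    arr = np.asarray(sd_log, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("sd_log must be >= 0")
    out = 1.0 - np.power(10.0, -arr)
    return float(out) if np.isscalar(sd_log) or arr.ndim == 0 else out


@dataclass
class RSDReport:
    per_metabolite: pd.DataFrame  # work_package, role, metabolite_id, sd_log, rsd
    biological: pd.DataFrame  # work_package, metabolite_id, sd_bio_log, rsd_biological, clamped
    summary: pd.DataFrame  # work_package, role, median rsd (aggregate)
    n_clamped: int = 0
    skipped_cells: list[tuple[str, str]] = field(default_factory=list)


def rsd_report(
    m: AbundanceMatrix,
    roles: tuple[str, ...] = ("vehicle_control", "pool"),
    aggregate: str = "median",
) -> RSDReport:
    """Per-work-package RSDs for control and pool samples.

    Cells with fewer than 2 samples are skipped with a note.  The biological
    RSD is derived per work package by variance subtraction (control total
    minus pool technical), clamped at zero.
    """
    if m.scale != "log10":
        raise ValidationError(f"rsd_report expects scale 'log10', got {m.scale!r}")
    if aggregate not in ("median", "mean"):
        raise ValidationError(f"aggregate must be 'median' or 'mean', got {aggregate!r}")
    s = m.samples
    rows = []
    sd_by_cell: dict[tuple[str, str], pd.Series] = {}
    skipped: list[tuple[str, str]] = []
    for wp in pd.unique(s["work_package"]):
        for role in roles:
            ids = list(s.index[(s["work_package"] == wp) & (s["role"] == role)])
            if len(ids) < 2:
                skipped.append((wp, role))
                continue
            sd = m.values.loc[ids].std(axis=0, ddof=1, skipna=True)
            sd_by_cell[(wp, role)] = sd
            rsd = rsd_from_sdlog(sd.to_numpy())
            for mid, sdv, rv in zip(sd.index, sd.to_numpy(), rsd):
                rows.append(
                    {"work_package": wp, "role": role, "metabolite_id": mid, "sd_log": sdv, "rsd": rv}
                )
    per_met = pd.DataFrame(rows, columns=["work_package", "role", "metabolite_id", "sd_log", "rsd"])

    bio_rows = []
    n_clamped = 0
    for wp in pd.unique(s["work_package"]):
        tot = sd_by_cell.get((wp, "vehicle_control"))
        tech = sd_by_cell.get((wp, "pool"))
        if tot is None or tech is None:
            continue
        var_bio = tot**2 - tech**2
        clamped = var_bio < 0
        n_clamped += int(clamped.sum())
        sd_bio = np.sqrt(var_bio.clip(lower=0.0))
        rsd_bio = rsd_from_sdlog(sd_bio.to_numpy())
        for mid, sdv, rv, cl in zip(sd_bio.index, sd_bio.to_numpy(), rsd_bio, clamped):
            bio_rows.append(
                {
                    "work_package": wp,
                    "metabolite_id": mid,
                    "sd_bio_log": sdv,
                    "rsd_biological": rv,
                    "clamped": bool(cl),
                }
            )
    biological = pd.DataFrame(
        bio_rows, columns=["work_package", "metabolite_id", "sd_bio_log", "rsd_biological", "clamped"]
    )
    if len(per_met):
        agg = getattr(per_met.groupby(["work_package", "role"], sort=False)["rsd"], aggregate)()
        summary = agg.rename(f"{aggregate}_rsd").reset_index()
    else:
        summary = pd.DataFrame(columns=["work_package", "role", f"{aggregate}_rsd"])
    return RSDReport(
        per_metabolite=per_met,
        biological=biological,
        summary=summary,
        n_clamped=n_clamped,
        skipped_cells=skipped,
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # metabolites x components
    explained_variance_fraction: np.ndarray
    dropped_metabolites: list[str] = field(default_factory=list)


def pca(
    m: AbundanceMatrix,
    n_components: int = 3,
    include_roles: tuple[str, ...] = ("vehicle_control", "treated"),
) -> PCAResult:
    """PCA of the standardized log10 matrix via full SVD.

    Zero-variance metabolites are dropped (noted in the result); each
    remaining metabolite is centered and scaled to unit variance (ddof=1).
    Sign convention: within each component the loading of largest magnitude
    is positive.
    """
    if m.scale != "log10":
        raise ValidationError(f"pca expects scale 'log10', got {m.scale!r}")
    ids = [sid for sid in m.values.index if m.samples.loc[sid, "role"] in include_roles]
    X = m.values.loc[ids]
    if len(ids) < 3:
        raise ValidationError(f"PCA needs >=3 samples, have {len(ids)}")
    sd = X.std(axis=0, ddof=1)
    dropped = list(sd.index[(sd == 0) | sd.isna()])
    X = X.drop(columns=dropped)
    if X.isna().any().any():
        raise ValidationError("PCA input contains missing values; filter or impute first")
    n_components = int(n_components)
    max_comp = min(len(ids) - 1, X.shape[1])
    if n_components > max_comp:
        raise ValidationError(f"n_components={n_components} exceeds limit {max_comp}")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    arr = Z.to_numpy(dtype=float)
    U, S, Vt = np.linalg.svd(arr, full_matrices=False)
    # fixed sign convention for determinism
    for k in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U[:, :n_components] * S[:n_components]
    total_var = float((S**2).sum())
    explained = (S[:n_components] ** 2) / total_var
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        loadings=pd.DataFrame(Vt[:n_components].T, index=X.columns, columns=comp_names),
        explained_variance_fraction=explained,
        dropped_metabolites=dropped,
    )
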