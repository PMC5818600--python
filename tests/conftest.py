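import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from metabomoa import (
    AbundanceMatrix,
    MetabolicProfile,
    MetabolitePanel,
    PanelEntry,
    SampleMeta,
)
from metabomoa.core_data import samples_frame

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_panel(metabolite_ids, met_class="energy", compartment="intracellular"):
    entries = [
        PanelEntry(
            metabolite_id=mid,
            name=mid,
            met_class=met_class,
            known=met_class != "unknown",
            compartment=compartment,
        )
        for mid in metabolite_ids
    ]
    return MetabolitePanel.from_entries(entries)


def make_matrix(values, roles, treatments=None, doses=None, work_packages=None, scale="raw",
                metabolite_ids=None, compartment="intracellular"):
    """Small-study factory: values is a 2-D array, roles a list per sample."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    metabolite_ids = metabolite_ids or [f"met_{j + 1:02d}" for j in range(m)]
    treatments = treatments or ["" if r != "treated" else "tx" for r in roles]
    doses = doses or ["none" if r != "treated" else "HD" for r in roles]
    work_packages = work_packages or ["wp01"] * n
    metas = [
        SampleMeta(
            sample_id=f"S{i + 1:02d}",
            role=roles[i],
            treatment=treatments[i],
            dose=doses[i],
            work_package=work_packages[i],
            compartment=compartment,
        )
        for i in range(n)
    ]
    vals = pd.DataFrame(values, index=[s.sample_id for s in metas], columns=metabolite_ids)
    vals.index.name = "sample_id"
    return AbundanceMatrix(
        values=vals,
        samples=samples_frame(metas),
        panel=make_panel(metabolite_ids, compartment=compartment),
        scale=scale,
    )


def make_profile(treatment, significant, metabolite_ids, dose="HD",
                 compartment="intracellular", alpha=0.05):
    """Synthetic profile: `significant` maps metabolite_id -> direction."""
    rows = []
    for mid in metabolite_ids:
        if mid in significant:
            d = significant[mid]
            rows.append(
                {"t_value": 5.0 if d == "up" else -5.0, "p_value": 1e-4,
                 "median_ratio": 2.0 if d == "up" else 0.5,
                 "significant": True, "direction": d, "degenerate": False}
            )
        else:
            rows.append(
                {"t_value": 0.1, "p_value": 0.9, "median_ratio": 1.0,
                 "significant": False, "direction": "none", "degenerate": False}
            )
    data = pd.DataFrame(rows, index=pd.Index(metabolite_ids, name="metabolite_id"))
    return MetabolicProfile(
        treatment=treatment, dose=dose, compartment=compartment, alpha=alpha, data=data
    )


@pytest.fixture(scope="session")
def ei_study():
    """One simulated enzyme-inducer study, normalized and HD-profiled."""
    import metabomoa as mm

    cfg = mm.scenario_library("enzyme_inducers")
    matrix, truth = mm.simulate_study(cfg, seed=7)
    logged, _ = mm.normalize_pipeline(matrix)
    profiles = mm.profile_all(logged, doses=("HD",))
    db = mm.ProfileDatabase.from_profiles(profiles, moa_labels=cfg.moa_labels)
    return {"cfg": cfg, "matrix": matrix, "truth": truth, "logged": logged,
            "profiles": profiles, "db": db}
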