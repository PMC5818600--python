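"""Synthetic HepG2-style metabolome studies with known ground truth.

The generator reproduces the statistical structure the downstream analysis
assumes, not instrument physics.  The value model, on the log10 scale, is

    log10 X[i, j] = log10 baseline[j] + batch(wp(i)) + bio[i, j] + tech[i, j]
                    + planted log10 fold(treatment(i), dose(i), j)

with multiplicative log-normal noise throughout.  Roles differ in which
terms they receive:

* vehicle controls and treated samples: batch + biological + technical noise;
* pool reference replicates: batch + technical noise only (the pool is one
  homogeneous material measured repeatedly, so its spread is purely
  technical — this is what lets technical and total variability be
  decomposed);
* blanks: medium without cells, ``baseline * blank_fraction`` with technical
  noise only.

Batch effects are a single multiplicative factor per work package shared by
every sample and metabolite in that package — the "different day, different
cell number" scale shift that within-sample median normalization removes.

Default noise levels (sd 0.032 technical, 0.040 biological on log10) are
chosen so that back-transformed relative standard deviations land where a
well-run targeted platform sits: pool RSD ~7%, control RSD ~11%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import (
    AbundanceMatrix,
    MetabolitePanel,
    PanelEntry,
    ValidationError,
    samples_frame,
    SampleMeta,
)

# Panel class allocations. The known/unknown totals (117+77 intracellular,
# 70+19 supernatant) match the profiling platform's published panel sizes;
# the per-class split is a fixed, lipid-dominant allocation.
_KNOWN_CLASS_COUNTS = {
    "intracellular": {
        "lipid": 45,
        "amino_acid": 25,
        "amino_acid_related": 12,
        "energy": 12,
        "carbohydrate": 8,
        "nucleobase": 7,
        "vitamin_cofactor": 5,
        "other": 3,
    },
    "supernatant": {
        "lipid": 20,
        "amino_acid": 22,
        "amino_acid_related": 8,
        "energy": 7,
        "carbohydrate": 5,
        "nucleobase": 4,
        "vitamin_cofactor": 2,
        "other": 2,
    },
}
_UNKNOWN_COUNTS = {"intracellular": 77, "supernatant": 19}
_PREFIX = {"intracellular": "ic", "supernatant": "sn"}


def default_panel(compartment: str = "intracellular") -> MetabolitePanel:
    """Deterministic metabolite panel for one compartment.

    Intracellular: 117 known + 77 unknown analytes; supernatant: 70 + 19.
    """
    if compartment not in _KNOWN_CLASS_COUNTS:
        raise ValidationError(f"unknown compartment {compartment!r}")
    prefix = _PREFIX[compartment]
    entries: list[PanelEntry] = []
    for met_class, n in _KNOWN_CLASS_COUNTS[compartment].items():
        for i in range(1, n + 1):
            mid = f"{prefix}_{met_class}_{i:03d}"
            entries.append(
                PanelEntry(
                    metabolite_id=mid,
                    name=f"{met_class.replace('_', ' ')} {i}",
                    met_class=met_class,
                    known=True,
                    compartment=compartment,
                )
            )
    for i in range(1, _UNKNOWN_COUNTS[compartment] + 1):
        mid = f"{prefix}_unknown_{i:03d}"
        entries.append(
            PanelEntry(
                metabolite_id=mid,
                name=f"unknown {i}",
                met_class="unknown",
                known=False,
                compartment=compartment,
            )
        )
    return MetabolitePanel.from_entries(entries)


@dataclass(frozen=True)
class SignatureMember:
    metabolite_id: str
    direction: str  # "up" | "down"
    hd_fold: float = 2.0
    ld_fold: float = 1.4


@dataclass
class PlantedSignature:
    """A named set of dose-monotone planted metabolite effects."""

    name: str
    members: list[SignatureMember]
    applies_to: list[str]

    def validate(self, panel: MetabolitePanel) -> None:
        ids = set(panel.metabolite_ids)
        for m in self.members:
            if m.metabolite_id not in ids:
                raise ValidationError(
                    f"signature {self.name!r} references unknown metabolite {m.metabolite_id!r}"
                )
            if m.direction not in ("up", "down"):
                raise ValidationError(f"signature {self.name!r}: bad direction {m.direction!r}")
            if m.hd_fold <= 0 or m.ld_fold <= 0:
                raise ValidationError(f"signature {self.name!r}: folds must be > 0")
            # dose monotonicity of the planted truth (folds are stored >= 1;
            # direction encodes the sign)
            if m.hd_fold < m.ld_fold:
                raise ValidationError(
                    f"signature {self.name!r}: hd_fold must be at least ld_fold "
                    f"({m.metabolite_id}: {m.hd_fold} < {m.ld_fold})"
                )


@dataclass
class NoiseModel:
    sd_tech_log10: float = 0.032
    sd_bio_log10: float = 0.040
    sd_batch_log10: float = 0.05

    def validate(self) -> None:
        for name in ("sd_tech_log10", "sd_bio_log10", "sd_batch_log10"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class SimulationConfig:
    """Everything needed to generate one study deterministically."""

    panel: MetabolitePanel
    treatments_by_package: dict[str, list[str]]
    n_vehicle_control: int = 16
    n_hd: int = 8
    n_ld: int = 8
    n_blank: int = 16
    n_pool: int = 16
    noise: NoiseModel = field(default_factory=NoiseModel)
    signatures: list[PlantedSignature] = field(default_factory=list)
    moa_labels: dict[str, str] = field(default_factory=dict)
    reference_treatments: list[str] = field(default_factory=list)
    blank_fraction: float = 0.01
    baseline_log10_range: tuple[float, float] = (2.0, 5.0)
    seed: int = 0

    def validate(self) -> None:
        self.noise.validate()
        treatments = [t for ts in self.treatments_by_package.values() for t in ts]
        if len(set(treatments)) != len(treatments):
            raise ValidationError("treatments must be unique across work packages")
        for sig in self.signatures:
            sig.validate(self.panel)
            for t in sig.applies_to:
                if t not in treatments:
                    raise ValidationError(
                        f"signature {sig.name!r} applies to unknown treatment {t!r}"
                    )

    @property
    def treatments(self) -> list[str]:
        return [t for ts in self.treatments_by_package.values() for t in ts]

    @property
    def compartment(self) -> str:
        return str(self.panel.table["compartment"].iloc[0])

    def general_pattern(self):
        """The scenario's general-toxicity signature as a matching Pattern.

        In the full workflow the general liver-toxicity pattern is an
        established resource derived once from the whole compound database;
        packaged scenarios carry their planted shared signature in that
        role.  Returns None if the scenario plants no general signature.
        """
        from .patterns import Pattern

        for sig in self.signatures:
            if sig.name == "general_toxicity":
                return Pattern(
                    name="general_toxicity",
                    moa_label="general_toxicity",
                    members=sorted((m.metabolite_id, m.direction) for m in sig.members),
                )
        return None


@dataclass
class PlantedTruth:
    """The simulator's record of what was planted, for recovery oracles."""

    effects: pd.DataFrame  # treatment, dose, metabolite_id, direction, log10_fold
    batch_offsets: dict[str, float]
    members: dict[str, list[tuple[str, str]]]  # signature name -> [(mid, direction)]

    def planted_set(self, signature: str) -> set[tuple[str, str]]:
        return set(self.members[signature])


def _effect_vector(
    cfg: SimulationConfig, treatment: str, dose: str, mid_index: pd.Index
) -> np.ndarray:
    eff = np.zeros(len(mid_index))
    for sig in cfg.signatures:
        if treatment not in sig.applies_to:
            continue
        for m in sig.members:
            fold = m.hd_fold if dose == "HD" else m.ld_fold
            lf = np.log10(fold)
            if m.direction == "down":
                lf = -lf
            eff[mid_index.get_loc(m.metabolite_id)] += lf
    return eff


def simulate_study(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[AbundanceMatrix, PlantedTruth]:
    """Generate one raw-scale study matrix plus its planted truth.

    Deterministic given ``seed`` (falls back to ``cfg.seed``); all randomness
    flows through a single ``numpy`` generator.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    mids = pd.Index(cfg.panel.metabolite_ids)
    m = len(mids)
    lo, hi = cfg.baseline_log10_range
    log_baseline = rng.uniform(lo, hi, size=m)
    noise = cfg.noise
    wps = list(cfg.treatments_by_package)
    batch = {wp: (rng.normal(0.0, noise.sd_batch_log10) if noise.sd_batch_log10 > 0 else 0.0) for wp in wps}
    comp = cfg.compartment

    metas: list[SampleMeta] = []
    rows: list[np.ndarray] = []

    def add(sample_id: str, role: str, treatment: str, dose: str, wp: str, log_row: np.ndarray) -> None:
        metas.append(
            SampleMeta(
                sample_id=sample_id,
                role=role,
                treatment=treatment,
                dose=dose,
                work_package=wp,
                compartment=comp,
            )
        )
        rows.append(log_row)

    def tech(n: int) -> np.ndarray:
        if noise.sd_tech_log10 == 0:
            return np.zeros((n, m))
        return rng.normal(0.0, noise.sd_tech_log10, size=(n, m))

    def bio(n: int) -> np.ndarray:
        if noise.sd_bio_log10 == 0:
            return np.zeros((n, m))
        return rng.normal(0.0, noise.sd_bio_log10, size=(n, m))

    effects_records: list[dict] = []
    for wp in wps:
        b = batch[wp]
        vc = log_baseline + b + bio(cfg.n_vehicle_control) + tech(cfg.n_vehicle_control)
        for i in range(cfg.n_vehicle_control):
            add(f"{wp}_VC_{i + 1:02d}", "vehicle_control", "", "none", wp, vc[i])
        pool = log_baseline + b + tech(cfg.n_pool)
        for i in range(cfg.n_pool):
            add(f"{wp}_POOL_{i + 1:02d}", "pool", "", "none", wp, pool[i])
        blank = log_baseline + np.log10(cfg.blank_fraction) + tech(cfg.n_blank)
        for i in range(cfg.n_blank):
            add(f"{wp}_BLANK_{i + 1:02d}", "blank", "", "none", wp, blank[i])
        for treatment in cfg.treatments_by_package[wp]:
            for dose, n_rep in (("LD", cfg.n_ld), ("HD", cfg.n_hd)):
                eff = _effect_vector(cfg, treatment, dose, mids)
                block = log_baseline + b + eff + bio(n_rep) + tech(n_rep)
                for i in range(n_rep):
                    add(f"{wp}_{treatment}_{dose}_{i + 1:02d}", "treated", treatment, dose, wp, block[i])
                nz = np.nonzero(eff)[0]
                for j in nz:
                    effects_records.append(
                        {
                            "treatment": treatment,
                            "dose": dose,
                            "metabolite_id": mids[j],
                            "direction": "up" if eff[j] > 0 else "down",
                            "log10_fold": eff[j],
                        }
                    )

    values = pd.DataFrame(
        np.power(10.0, np.vstack(rows)), index=[s.sample_id for s in metas], columns=mids
    )
    values.index.name = "sample_id"
    matrix = AbundanceMatrix(values=values, samples=samples_frame(metas), panel=cfg.panel, scale="raw")
    effects = pd.DataFrame(
        effects_records,
        columns=["treatment", "dose", "metabolite_id", "direction", "log10_fold"],
    )
    truth = PlantedTruth(
        effects=effects,
        batch_offsets=batch,
        members={sig.name: [(m.metabolite_id, m.direction) for m in sig.members] for sig in cfg.signatures},
    )
    return matrix, truth


# -- packaged scenarios ------------------------------------------------------

# Signature class compositions (number of members drawn from each panel
# class).  General toxicity: 38 members — 9 identified lipids plus 16
# unknowns (lipids pending identification), 6 energy metabolites, 5 amino
# acids, 1 amino-acid-related, 1 carbohydrate.  Enzyme inducer: 9 members —
# 5 lipid/complex-lipid (incl. triacylglycerols), 3 amino acids, 1 related.
# Peroxisome proliferator: 12 members — 6 lipids, 3 amino acids, 1 related,
# 2 other.
_GENERAL_COMPOSITION = {
    "lipid": 9,
    "unknown": 16,
    "energy": 6,
    "amino_acid": 5,
    "amino_acid_related": 1,
    "carbohydrate": 1,
}
_EI_COMPOSITION = {"lipid": 5, "amino_acid": 3, "amino_acid_related": 1}
_PP_COMPOSITION = {"lipid": 6, "amino_acid": 3, "amino_acid_related": 1, "other": 2}

SCENARIOS = ("enzyme_inducers", "peroxisome_proliferators", "general_toxicity", "null_study")


def _build_signature(
    name: str,
    composition: dict[str, int],
    panel: MetabolitePanel,
    used: set[str],
    applies_to: list[str],
    hd_fold: float = 2.0,
    ld_fold: float = 1.4,
) -> PlantedSignature:
    """Pick members deterministically: first unused panel ids of each class,
    directions alternating up/down within the signature."""
    members: list[SignatureMember] = []
    k = 0
    for met_class, n in composition.items():
        candidates = [
            mid
            for mid in panel.metabolite_ids
            if panel.table.loc[mid, "met_class"] == met_class and mid not in used
        ]
        if len(candidates) < n:
            raise ValidationError(
                f"panel has only {len(candidates)} free {met_class!r} metabolites, need {n}"
            )
        for mid in candidates[:n]:
            used.add(mid)
            members.append(
                SignatureMember(
                    metabolite_id=mid,
                    direction="up" if k % 2 == 0 else "down",
                    hd_fold=hd_fold,
                    ld_fold=ld_fold,
                )
            )
            k += 1
    return PlantedSignature(name=name, members=members, applies_to=applies_to)


def scenario_library(name: str, seed: int = 0) -> SimulationConfig:
    """Ready-to-run study configurations.

    * ``enzyme_inducers`` — 3 enzyme-inducer references + 2 further inducers,
      1 peroxisome proliferator and 1 untargeted compound; inducer and
      proliferator signatures planted on their compound sets, a shared
      general-toxicity signature on all treatments.
    * ``peroxisome_proliferators`` — the mirror image (3 + 2 proliferators,
      1 inducer, 1 untargeted).
    * ``general_toxicity`` — 6 hepatotoxicants all carrying the shared
      signature only.
    * ``null_study`` — one sham treatment, nothing planted.
    """
    panel = default_panel("intracellular")
    used: set[str] = set()
    if name == "null_study":
        cfg = SimulationConfig(
            panel=panel,
            treatments_by_package={"wp01": ["sham_1"]},
            moa_labels={"sham_1": "none"},
            seed=seed,
        )
    elif name == "general_toxicity":
        treatments_by_package = {
            "wp01": ["hepatotox_1", "hepatotox_2"],
            "wp02": ["hepatotox_3", "hepatotox_4"],
            "wp03": ["hepatotox_5", "hepatotox_6"],
        }
        all_t = [t for ts in treatments_by_package.values() for t in ts]
        general = _build_signature("general_toxicity", _GENERAL_COMPOSITION, panel, used, all_t)
        cfg = SimulationConfig(
            panel=panel,
            treatments_by_package=treatments_by_package,
            signatures=[general],
            moa_labels={t: "general_toxicity" for t in all_t},
            seed=seed,
        )
    elif name in ("enzyme_inducers", "peroxisome_proliferators"):
        if name == "enzyme_inducers":
            focus, focus_comp = "enzyme_inducer", _EI_COMPOSITION
            other, other_comp = "peroxisome_proliferator", _PP_COMPOSITION
            focus_prefix, other_prefix = "inducer", "proliferator"
        else:
            focus, focus_comp = "peroxisome_proliferator", _PP_COMPOSITION
            other, other_comp = "enzyme_inducer", _EI_COMPOSITION
            focus_prefix, other_prefix = "proliferator", "inducer"
        refs = [f"{focus_prefix}_ref_{i}" for i in (1, 2, 3)]
        tests = [f"{focus_prefix}_test_{i}" for i in (1, 2)]
        others = [f"{other_prefix}_1"]
        untargeted = ["untargeted_1"]
        treatments_by_package = {
            "wp01": [refs[0], refs[1]],
            "wp02": [refs[2], tests[0]],
            "wp03": [tests[1], others[0]],
            "wp04": [untargeted[0]],
        }
        all_t = [t for ts in treatments_by_package.values() for t in ts]
        general = _build_signature("general_toxicity", _GENERAL_COMPOSITION, panel, used, all_t)
        focus_sig = _build_signature(focus, focus_comp, panel, used, refs + tests)
        other_sig = _build_signature(other, other_comp, panel, used, others)
        labels = {t: focus for t in refs + tests}
        labels.update({t: other for t in others})
        labels["untargeted_1"] = "none"
        cfg = SimulationConfig(
            panel=panel,
            treatments_by_package=treatments_by_package,
            signatures=[general, focus_sig, other_sig],
            moa_labels=labels,
            reference_treatments=refs,
            seed=seed,
        )
    else:
        raise ValidationError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    cfg.validate()
    return cfg
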