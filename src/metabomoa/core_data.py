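"""Domain types and validated readers/writers for metabolome study tables.

A study is exchanged as three tab-separated UTF-8 files:

* ``values.tsv``  — rows are samples, columns are metabolites, first line a
  ``# scale=<scale>`` tag; missing values written as ``NA``.
* ``samples.tsv`` — one row of metadata per sample (role, treatment, dose,
  work package, compartment).
* ``panel.tsv``   — one row per metabolite (name, class, known flag,
  compartment).

Sample and metabolite order is preserved exactly as read; nothing is sorted
behind the caller's back, so downstream tie-breaks and PCA signs are
reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MET_CLASSES = (
    "lipid",
    "amino_acid",
    "amino_acid_related",
    "energy",
    "carbohydrate",
    "nucleobase",
    "vitamin_cofactor",
    "other",
    "unknown",
)
COMPARTMENTS = ("supernatant", "intracellular")
ROLES = ("vehicle_control", "treated", "pool", "blank")
DOSES = ("none", "LD", "HD")
SCALES = ("raw", "pool_ratio", "median_ratio", "log10")

#: scales on which values must be non-negative (log10 may be negative)
_NONNEGATIVE_SCALES = ("raw", "pool_ratio", "median_ratio")

MISSING_TOKEN = "NA"


class ValidationError(ValueError):
    """Raised when a table violates a structural invariant."""


def _check_unique(values, what: str) -> None:
    s = pd.Series(values)
    dup = s[s.duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"duplicated {what}: {dup}")


@dataclass(frozen=True)
class PanelEntry:
    metabolite_id: str
    name: str
    met_class: str
    known: bool
    compartment: str


@dataclass
class MetabolitePanel:
    """The analyte universe: identity, chemical class, known flag, compartment.

    ``table`` is indexed by ``metabolite_id`` with columns
    ``name, met_class, known, compartment``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @classmethod
    def from_entries(cls, entries: list[PanelEntry]) -> "MetabolitePanel":
        df = pd.DataFrame([dataclasses.asdict(e) for e in entries])
        return cls(df.set_index("metabolite_id"))

    def validate(self) -> None:
        required = {"name", "met_class", "known", "compartment"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"panel table missing columns: {sorted(missing)}")
        # uniqueness within compartment
        for comp, sub in self.table.groupby("compartment"):
            _check_unique(sub.index, f"metabolite_id in compartment {comp!r}")
        bad_class = set(self.table["met_class"]) - set(MET_CLASSES)
        if bad_class:
            raise ValidationError(f"unknown metabolite classes: {sorted(bad_class)}")
        bad_comp = set(self.table["compartment"]) - set(COMPARTMENTS)
        if bad_comp:
            raise ValidationError(f"unknown compartments: {sorted(bad_comp)}")
        known = self.table["known"].astype(bool)
        is_unknown_class = self.table["met_class"] == "unknown"
        clash = self.table.index[known == is_unknown_class].tolist()
        if clash:
            raise ValidationError(
                f"known flag must be False exactly for class 'unknown'; offenders: {clash[:10]}"
            )

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.table.index)

    def class_counts(self) -> pd.Series:
        return self.table["met_class"].value_counts()

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolitePanel):
            return NotImplemented
        return self.table.equals(other.table)


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    role: str
    treatment: str
    dose: str
    work_package: str
    compartment: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"{self.sample_id}: unknown role {self.role!r}")
        if self.dose not in DOSES:
            raise ValidationError(f"{self.sample_id}: unknown dose {self.dose!r}")
        if self.role == "treated":
            if not self.treatment:
                raise ValidationError(f"{self.sample_id}: treated sample needs a treatment")
            if self.dose not in ("LD", "HD"):
                raise ValidationError(f"{self.sample_id}: treated sample needs dose LD or HD")
        else:
            if self.dose != "none":
                raise ValidationError(
                    f"{self.sample_id}: role {self.role} must have dose 'none'"
                )


def samples_frame(metas: list[SampleMeta]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(m) for m in metas])
    return df.set_index("sample_id")


@dataclass
class AbundanceMatrix:
    """Samples x metabolites values plus per-sample metadata.

    ``values`` is a float DataFrame (index = sample_id, columns =
    metabolite_id); missing measurements are NaN, never silent zeros.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    panel: MetabolitePanel
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}")
        _check_unique(self.values.index, "sample_id in values")
        _check_unique(self.values.columns, "metabolite_id in values")
        _check_unique(self.samples.index, "sample_id in metadata")
        vs, ms = set(self.values.index), set(self.samples.index)
        if vs != ms:
            only_meta = sorted(ms - vs)
            only_vals = sorted(vs - ms)
            raise ValidationError(
                "sample_id mismatch between values and metadata; "
                f"only in metadata: {only_meta[:10]}; only in values: {only_vals[:10]}"
            )
        pv = set(self.values.columns) - set(self.panel.metabolite_ids)
        if pv:
            raise ValidationError(f"metabolites in values absent from panel: {sorted(pv)[:10]}")
        vp = set(self.panel.metabolite_ids) - set(self.values.columns)
        if vp:
            raise ValidationError(f"panel metabolites absent from values: {sorted(vp)[:10]}")
        if self.scale in _NONNEGATIVE_SCALES:
            arr = self.values.to_numpy(dtype=float)
            if np.nanmin(arr, initial=0.0) < 0:
                rows, cols = np.where(arr < 0)
                loc = [
                    (self.values.index[r], self.values.columns[c])
                    for r, c in zip(rows[:5], cols[:5])
                ]
                raise ValidationError(f"negative values on scale {self.scale!r} at {loc}")
        for sid in self.samples.index:
            row = self.samples.loc[sid]
            SampleMeta(
                sample_id=str(sid),
                role=row["role"],
                treatment=row["treatment"],
                dose=row["dose"],
                work_package=row["work_package"],
                compartment=row["compartment"],
            )

    # -- convenience selectors ------------------------------------------------
    def sample_ids(self, role: str | None = None, work_package: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        if role is not None:
            mask &= self.samples["role"] == role
        if work_package is not None:
            mask &= self.samples["work_package"] == work_package
        return list(self.samples.index[mask])

    def replace_values(self, values: pd.DataFrame, scale: str) -> "AbundanceMatrix":
        return AbundanceMatrix(values=values, samples=self.samples.copy(), panel=self.panel, scale=scale)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceMatrix):
            return NotImplemented
        return (
            self.scale == other.scale
            and self.panel == other.panel
            and self.samples.equals(other.samples)
            and self.values.shape == other.values.shape
            and list(self.values.index) == list(other.values.index)
            and list(self.values.columns) == list(other.values.columns)
            and np.allclose(
                self.values.to_numpy(float),
                other.values.to_numpy(float),
                rtol=1e-9,
                atol=0.0,
                equal_nan=True,
            )
        )


@dataclass
class StudyDesign:
    """Replicate bookkeeping per work package, plus soft QC flags.

    Flags report groups too small for downstream statistics (minimum 2 per
    treated group, 2 pools and 2 vehicle controls per work package); they are
    warnings, not errors, so QC-only datasets still load.
    """

    counts: pd.DataFrame  # work_package, role, treatment, dose, n
    flags: list[str] = field(default_factory=list)
    treatments: list[str] = field(default_factory=list)


def validate_design(m: AbundanceMatrix, min_group: int = 2) -> StudyDesign:
    """Summarize replicate counts per role/treatment/dose/work package.

    Never raises for small groups: violations are returned as flags.
    """
    s = m.samples
    counts = (
        s.groupby(["work_package", "role", "treatment", "dose"], sort=False)
        .size()
        .rename("n")
        .reset_index()
    )
    flags: list[str] = []
    for _, row in counts.iterrows():
        if row["role"] == "treated" and row["n"] < min_group:
            flags.append(
                f"treated group {row['treatment']}/{row['dose']} in {row['work_package']} "
                f"has n={row['n']} < {min_group}"
            )
    for wp in pd.unique(s["work_package"]):
        sub = s[s["work_package"] == wp]
        n_pool = int((sub["role"] == "pool").sum())
        n_vc = int((sub["role"] == "vehicle_control").sum())
        if n_pool < min_group:
            flags.append(f"work package {wp} has {n_pool} pool samples (<{min_group}); RSD not computable")
        if n_vc < min_group:
            flags.append(f"work package {wp} has {n_vc} vehicle controls (<{min_group})")
    treatments = sorted(set(s.loc[s["role"] == "treated", "treatment"]))
    return StudyDesign(counts=counts, flags=flags, treatments=treatments)


# -- file IO -----------------------------------------------------------------

_VALUES = "values.tsv"
_SAMPLES = "samples.tsv"
_PANEL = "panel.tsv"


def write_abundance_table(m: AbundanceMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write values/samples/panel TSVs; loss-free at 12 significant digits."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "values": out / _VALUES,
        "samples": out / _SAMPLES,
        "panel": out / _PANEL,
    }
    with open(paths["values"], "w", encoding="utf-8") as fh:
        fh.write(f"# scale={m.scale}\n")
        m.values.to_csv(
            fh, sep="\t", index_label="sample_id", na_rep=MISSING_TOKEN, float_format="%.12g"
        )
    m.samples.to_csv(paths["samples"], sep="\t", index_label="sample_id")
    m.panel.table.to_csv(paths["panel"], sep="\t", index_label="metabolite_id")
    return paths


def _read_meta_tsv(path: Path, index_col: str) -> pd.DataFrame:
    # keep empty strings as "" (not NaN): empty treatment is meaningful
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    if index_col not in df.columns:
        raise ValidationError(f"{path}: missing column {index_col!r}")
    return df.set_index(index_col)


def read_abundance_table(
    values_path: str | Path,
    meta_path: str | Path,
    panel_path: str | Path,
) -> AbundanceMatrix:
    """Read and cross-validate the three study files.

    The scale tag is read from a leading ``# scale=`` line in the values file
    and defaults to ``raw`` if absent.
    """
    values_path, meta_path, panel_path = Path(values_path), Path(meta_path), Path(panel_path)
    scale = "raw"
    with open(values_path, encoding="utf-8") as fh:
        first = fh.readline()
        skip = 0
        if first.startswith("#"):
            skip = 1
            tag = first.lstrip("#").strip()
            if tag.startswith("scale="):
                scale = tag.split("=", 1)[1].strip()
    values = pd.read_csv(
        values_path,
        sep="\t",
        skiprows=skip,
        index_col="sample_id",
        na_values=[MISSING_TOKEN],
        keep_default_na=False,
    )
    values = values.astype(float)
    values.index = values.index.astype(str)

    meta = _read_meta_tsv(meta_path, "sample_id")
    panel_df = _read_meta_tsv(panel_path, "metabolite_id")
    panel_df["known"] = panel_df["known"].map({"True": True, "False": False})
    if panel_df["known"].isna().any():
        raise ValidationError(f"{panel_path}: 'known' column must be True/False")
    panel = MetabolitePanel(panel_df)
    return AbundanceMatrix(values=values, samples=meta, panel=panel, scale=scale)
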