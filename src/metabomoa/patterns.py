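"""Profile similarity, PWC ranking, and mode-of-action signature patterns.

The inference chain is:

1. *Similarity* — two treatments are compared by the Pearson correlation of
   their per-metabolite Welch t-value vectors; a pair-wise comparison (PWC)
   ranks a whole profile database against a query, replicates of the same
   condition landing at the top when the assay is reproducible.
2. *General-toxicity pattern* — metabolites significantly regulated in the
   same direction in most high-dose profiles are unspecific "sick cell"
   responses; they are extracted once and subtracted from every
   mode-of-action candidate to sharpen specificity.
3. *MoA pattern derivation* — metabolites significant with identical
   direction in all (>=3) reference compounds of one mode of action, minus
   the general pattern, then greedily refined (add/remove one metabolite at
   a time) to maximize Youden's J = sensitivity + specificity - 1 over the
   labelled non-reference compounds.
4. *Matching* — a profile matches a pattern when the number of members
   significant in the expected direction is larger than chance: the match
   p value is the one-sided binomial tail P(Bin(m, p0) >= k) with
   p0 = alpha/2, the null probability that a metabolite is significant in a
   given direction.  One failing metabolite in a small pattern yields p in
   the 0.1-0.2 range, so near-misses remain visible rather than vanishing
   into a hard cutoff.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import ValidationError
from .profiling import MetabolicProfile

ProfileKey = tuple[str, str, str]  # (treatment, dose, compartment)


@dataclass
class ProfileDatabase:
    """Flat-file-backed store of metabolic profiles with optional MoA labels."""

    profiles: dict[ProfileKey, MetabolicProfile] = field(default_factory=dict)
    moa_labels: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_profiles(
        cls, profiles: list[MetabolicProfile], moa_labels: dict[str, str] | None = None
    ) -> "ProfileDatabase":
        db = cls(moa_labels=dict(moa_labels or {}))
        for p in profiles:
            db.add(p)
        return db

    def add(self, p: MetabolicProfile) -> None:
        if p.key in self.profiles:
            raise ValidationError(f"duplicate profile key {p.key}")
        self.profiles[p.key] = p

    def hd_profiles(self) -> list[MetabolicProfile]:
        return [p for p in self.profiles.values() if p.dose == "HD"]

    def get(self, key: ProfileKey) -> MetabolicProfile:
        return self.profiles[key]

    def __len__(self) -> int:
        return len(self.profiles)


@dataclass
class SimilarityResult:
    key_a: ProfileKey
    key_b: ProfileKey
    r: float
    n_shared: int


def profile_similarity(a: MetabolicProfile, b: MetabolicProfile) -> SimilarityResult:
    """Pearson correlation of two t-value profiles over shared metabolites.

    Degenerate metabolites (undefined t) on either side are excluded; at
    least 3 shared metabolites are required.
    """
    ta = a.t_values(drop_degenerate=True)
    tb = b.t_values(drop_degenerate=True)
    shared = ta.index.intersection(tb.index)
    if len(shared) < 3:
        raise ValidationError(
            f"only {len(shared)} shared non-degenerate metabolites between "
            f"{a.key} and {b.key} (<3)"
        )
    x = ta.loc[shared].to_numpy(dtype=float)
    y = tb.loc[shared].to_numpy(dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    denom = np.sqrt((xm**2).sum() * (ym**2).sum())
    if denom == 0:
        raise ValidationError(f"zero-variance t profile between {a.key} and {b.key}")
    r = float(np.clip((xm * ym).sum() / denom, -1.0, 1.0))
    return SimilarityResult(key_a=a.key, key_b=b.key, r=r, n_shared=len(shared))


@dataclass
class PWCRanking:
    query: ProfileKey
    entries: list[tuple[ProfileKey, float, int]]  # (key, r, rank from 1)
    omitted: list[tuple[ProfileKey, str]] = field(default_factory=list)

    def rank_of(self, key: ProfileKey) -> int:
        for k, _, rank in self.entries:
            if k == key:
                return rank
        raise KeyError(key)


def pwc_rank(
    query: MetabolicProfile | ProfileKey, db: ProfileDatabase
) -> PWCRanking:
    """Rank every other database profile by t-profile correlation with the query.

    Ties broken deterministically by (r descending, treatment, dose
    ascending); pairs with too few shared metabolites are omitted and
    reported.
    """
    q = db.get(query) if not isinstance(query, MetabolicProfile) else query
    results: list[tuple[ProfileKey, float]] = []
    omitted: list[tuple[ProfileKey, str]] = []
    for key, p in db.profiles.items():
        if key == q.key:
            continue
        try:
            results.append((key, profile_similarity(q, p).r))
        except ValidationError as e:
            omitted.append((key, str(e)))
    results.sort(key=lambda kr: (-kr[1], kr[0][0], kr[0][1]))
    entries = [(key, r, i + 1) for i, (key, r) in enumerate(results)]
    return PWCRanking(query=q.key, entries=entries, omitted=omitted)


def similarity_matrix(db: ProfileDatabase) -> pd.DataFrame:
    """Square symmetric matrix of pairwise t-profile correlations."""
    keys = list(db.profiles)
    labels = ["|".join(k) for k in keys]
    mat = pd.DataFrame(np.eye(len(keys)), index=labels, columns=labels)
    for i, ka in enumerate(keys):
        for j in range(i + 1, len(keys)):
            r = profile_similarity(db.profiles[ka], db.profiles[keys[j]]).r
            mat.iloc[i, j] = mat.iloc[j, i] = r
    return mat


@dataclass
class Pattern:
    """A named set of (metabolite, expected direction) pairs for one MoA."""

    name: str
    moa_label: str
    members: list[tuple[str, str]]  # (metabolite_id, "up"|"down")

    def __post_init__(self) -> None:
        ids = [m for m, _ in self.members]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"pattern {self.name!r}: duplicate members")
        bad = [d for _, d in self.members if d not in ("up", "down")]
        if bad:
            raise ValidationError(f"pattern {self.name!r}: directions must be up/down")

    @property
    def member_ids(self) -> set[str]:
        return {m for m, _ in self.members}

    def __len__(self) -> int:
        return len(self.members)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "moa_label": self.moa_label,
            "members": [
                {"metabolite_id": m, "direction": d} for m, d in self.members
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "Pattern":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            name=payload["name"],
            moa_label=payload["moa_label"],
            members=[(m["metabolite_id"], m["direction"]) for m in payload["members"]],
        )


@dataclass
class MatchResult:
    pattern: str
    profile: ProfileKey
    k_matched: int
    m: int
    match_p: float
    matched: bool


def match_pattern(
    pattern: Pattern,
    profile: MetabolicProfile,
    p0: float = 0.025,
    match_alpha: float = 0.05,
) -> MatchResult:
    """Binomial match test of a profile against a pattern.

    k counts members significant in their expected direction; the match
    p value is the exact one-sided tail P(Bin(m, p0) >= k).  Pattern
    metabolites missing or degenerate in the profile count as unmatched.
    """
    if len(pattern) == 0:
        raise ValidationError(f"pattern {pattern.name!r} is empty")
    sig = profile.significant_set()
    k = sum((mid, d) in sig for mid, d in pattern.members)
    m = len(pattern)
    match_p = float(stats.binom.sf(k - 1, m, p0))  # == 1.0 at k=0
    return MatchResult(
        pattern=pattern.name,
        profile=profile.key,
        k_matched=k,
        m=m,
        match_p=match_p,
        matched=bool(match_p < match_alpha),
    )


def derive_general_pattern(
    db: ProfileDatabase, hd_only: bool = True, min_fraction: float = 0.75
) -> Pattern:
    """Extract metabolites concordantly regulated in most treatments.

    A metabolite joins the general-toxicity pattern when it is significant in
    the same direction in at least ``min_fraction`` of the (high-dose)
    profiles.
    """
    profiles = db.hd_profiles() if hd_only else list(db.profiles.values())
    if len(profiles) < 3:
        raise ValidationError(f"need >=3 profiles to derive a general pattern, have {len(profiles)}")
    n = len(profiles)
    counts: dict[tuple[str, str], int] = {}
    for p in profiles:
        for entry in p.significant_set():
            counts[entry] = counts.get(entry, 0) + 1
    members = sorted(
        (mid, d) for (mid, d), c in counts.items() if c / n >= min_fraction
    )
    return Pattern(name="general_toxicity", moa_label="general_toxicity", members=members)


def _concordant_in_refs(
    refs: list[MetabolicProfile], min_refs: int
) -> dict[str, str]:
    """Metabolite -> direction significant-concordant in >= min_refs references."""
    counts: dict[tuple[str, str], int] = {}
    for p in refs:
        for entry in p.significant_set():
            counts[entry] = counts.get(entry, 0) + 1
    out: dict[str, str] = {}
    for (mid, d), c in sorted(counts.items()):
        if c >= min_refs and mid not in out:
            out[mid] = d
        elif c >= min_refs:
            # both directions reach the threshold (possible only if min_refs
            # <= len(refs)/2); keep the more frequent, ties to 'down' dropped
            if counts.get((mid, "up"), 0) < c:
                out[mid] = d
    return out


def derive_moa_pattern(
    db: ProfileDatabase,
    reference_treatments: list[str],
    general: Pattern | None,
    labels: dict[str, str] | None = None,
    moa_label: str | None = None,
    match_alpha: float = 0.05,
    refine: bool = True,
) -> Pattern:
    """Derive a MoA signature from >=3 reference compounds.

    Candidate members are significant with identical direction in *all*
    reference high-dose profiles; general-toxicity members are subtracted;
    the result is refined against the labelled database.
    """
    if len(reference_treatments) < 3:
        raise ValidationError(
            f"MoA derivation needs >=3 reference compounds, got {len(reference_treatments)}"
        )
    labels = labels if labels is not None else db.moa_labels
    refs = [p for p in db.hd_profiles() if p.treatment in reference_treatments]
    if len(refs) < 3:
        missing = set(reference_treatments) - {p.treatment for p in refs}
        raise ValidationError(f"missing HD profiles for reference treatments: {sorted(missing)}")
    if moa_label is None:
        ref_labels = {labels.get(t) for t in reference_treatments}
        ref_labels.discard(None)
        if len(ref_labels) != 1:
            raise ValidationError(
                f"reference treatments carry inconsistent MoA labels: {sorted(map(str, ref_labels))}"
            )
        moa_label = ref_labels.pop()
    general_ids = general.member_ids if general is not None else set()
    concordant_all = _concordant_in_refs(refs, min_refs=len(refs))
    members = sorted(
        (mid, d) for mid, d in concordant_all.items() if mid not in general_ids
    )
    candidate = Pattern(name=f"{moa_label}_pattern", moa_label=moa_label, members=members)
    if not refine:
        return candidate
    return refine_pattern(
        candidate, db, labels=labels, reference_treatments=reference_treatments,
        match_alpha=match_alpha,
    )


def _youden(
    pattern: Pattern,
    positives: list[MetabolicProfile],
    negatives: list[MetabolicProfile],
    match_alpha: float,
) -> float:
    if len(pattern) == 0:
        return -1.0
    sens = (
        np.mean([match_pattern(pattern, p, match_alpha=match_alpha).matched for p in positives])
        if positives
        else 1.0
    )
    spec = (
        np.mean([not match_pattern(pattern, p, match_alpha=match_alpha).matched for p in negatives])
        if negatives
        else 1.0
    )
    return float(sens + spec - 1.0)


def refine_pattern(
    candidate: Pattern,
    db: ProfileDatabase,
    labels: dict[str, str] | None = None,
    reference_treatments: list[str] | None = None,
    match_alpha: float = 0.05,
    max_steps: int = 500,
) -> Pattern:
    """Greedy hill-climb on Youden's J = sensitivity + specificity - 1.

    Sensitivity is scored on labelled same-MoA high-dose profiles excluding
    the reference compounds (they defined the candidate and would make the
    score circular); specificity on labelled different-MoA profiles.  Moves
    are single-member removals, or additions of any metabolite significant-
    concordant in at least two references.  The move with the largest strict
    J gain is taken; ties prefer the smaller pattern, then the
    lexicographically smallest metabolite id.  Deterministic, and J never
    decreases.
    """
    if len(candidate) == 0:
        raise ValidationError("cannot refine an empty pattern")
    labels = labels if labels is not None else db.moa_labels
    reference_treatments = reference_treatments or []
    refs = [p for p in db.hd_profiles() if p.treatment in reference_treatments]
    eval_profiles = [
        p
        for p in db.hd_profiles()
        if p.treatment in labels and p.treatment not in reference_treatments
    ]
    positives = [p for p in eval_profiles if labels[p.treatment] == candidate.moa_label]
    negatives = [p for p in eval_profiles if labels[p.treatment] != candidate.moa_label]
    if not positives and not negatives:
        # nothing to score against; the candidate is returned unchanged
        import warnings

        warnings.warn(
            f"pattern {candidate.name!r}: no labelled non-reference compounds; "
            "refinement skipped",
            stacklevel=2,
        )
        return candidate

    addable = _concordant_in_refs(refs, min_refs=2) if len(refs) >= 2 else {}
    current = list(candidate.members)
    current_j = _youden(
        Pattern(candidate.name, candidate.moa_label, current), positives, negatives, match_alpha
    )
    for _ in range(max_steps):
        moves: list[tuple[float, int, str, list[tuple[str, str]]]] = []
        for mid, d in current:
            if len(current) == 1:
                continue  # never empty the pattern
            trial = [x for x in current if x != (mid, d)]
            j = _youden(Pattern(candidate.name, candidate.moa_label, trial), positives, negatives, match_alpha)
            moves.append((j, len(trial), mid, trial))
        member_ids = {m for m, _ in current}
        for mid, d in sorted(addable.items()):
            if mid in member_ids:
                continue
            trial = sorted(current + [(mid, d)])
            j = _youden(Pattern(candidate.name, candidate.moa_label, trial), positives, negatives, match_alpha)
            moves.append((j, len(trial), mid, trial))
        if not moves:
            break
        # best strict improvement; ties -> smaller pattern, then metabolite id
        moves.sort(key=lambda t: (-t[0], t[1], t[2]))
        best_j, _, _, best_members = moves[0]
        if best_j <= current_j + 1e-12:
            break
        current, current_j = best_members, best_j
    return Pattern(name=candidate.name, moa_label=candidate.moa_label, members=sorted(current))


def write_matches(results: list[MatchResult], path: str | Path) -> None:
    rows = [
        {
            "pattern": r.pattern,
            "treatment": r.profile[0],
            "dose": r.profile[1],
            "compartment": r.profile[2],
            "k_matched": r.k_matched,
            "m": r.m,
            "match_p": r.match_p,
            "matched": r.matched,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
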