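"""End-to-end study workflows: simulate -> normalize -> profile -> patterns.

Thin compositions of the library modules used by the CLI examples, the test
suite and the reproduction script.  Each function runs the full pipeline on
packaged scenarios across a range of seeds and reduces the results to the
quantity of interest.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable

from .normalize import normalize_pipeline
from .patterns import ProfileDatabase, derive_general_pattern, derive_moa_pattern
from .profiling import count_changed, profile_all, welch_profile
from .simulate import scenario_library, simulate_study


def null_significant_fraction(seeds: Iterable[int], alpha: float = 0.05) -> tuple[float, int]:
    """Pooled fraction of metabolites flagged significant under the null.

    Simulates the ``null_study`` scenario once per seed, Welch-profiles the
    sham treatment (8 HD vs 16 controls) and pools the per-metabolite test
    outcomes.  Returns (fraction, number of metabolite-tests).
    """
    cfg = scenario_library("null_study")
    n_sig = n_tot = 0
    for seed in seeds:
        matrix, _ = simulate_study(cfg, seed=seed)
        logged, _ = normalize_pipeline(matrix)
        profile = welch_profile(logged, "sham_1", "HD", alpha=alpha)
        n_sig += count_changed(profile)
        n_tot += int((~profile.data["degenerate"]).sum())
    return n_sig / n_tot, n_tot


def moa_pattern_sizes(scenario: str, seeds: Iterable[int]) -> list[int]:
    """Derived MoA pattern size per seed for a packaged MoA scenario.

    Per seed: simulate, normalize, profile all treatments at high dose,
    derive the MoA pattern from the scenario's three reference compounds
    with the scenario's general pattern subtracted, refine, and record the
    member count.
    """
    cfg = scenario_library(scenario)
    general = cfg.general_pattern()
    sizes = []
    for seed in seeds:
        matrix, _ = simulate_study(cfg, seed=seed)
        logged, _ = normalize_pipeline(matrix)
        db = ProfileDatabase.from_profiles(
            profile_all(logged, doses=("HD",)), moa_labels=cfg.moa_labels
        )
        pattern = derive_moa_pattern(db, cfg.reference_treatments, general)
        sizes.append(len(pattern))
    return sizes


def general_pattern_sizes(seeds: Iterable[int], min_fraction: float = 0.75) -> list[int]:
    """Derived general-toxicity pattern size per seed."""
    cfg = scenario_library("general_toxicity")
    sizes = []
    for seed in seeds:
        matrix, _ = simulate_study(cfg, seed=seed)
        logged, _ = normalize_pipeline(matrix)
        db = ProfileDatabase.from_profiles(profile_all(logged, doses=("HD",)))
        sizes.append(len(derive_general_pattern(db, min_fraction=min_fraction)))
    return sizes


def modal_count(sizes: list[int]) -> int:
    """Most frequent value; ties broken toward the smaller value."""
    counts = Counter(sizes)
    best = max(counts.values())
    return min(v for v, c in counts.items() if c == best)
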