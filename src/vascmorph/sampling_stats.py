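"""Systematic random sampling and dual-label perfusion-efficiency statistics.

Systematic random sampling is the stereological design of choice for
unbiased field-of-view selection: one uniform random start, then evenly
spaced picks, giving every candidate the same inclusion probability
``n_select / n_candidates``.

Perfusion efficiency of an intravascular contrast agent is assessed against
an independent endothelial label (lectin): every capillary found by either
label is classified as double-positive (``pp``: contrast+/lectin+),
contrast-only (``pm``) or lectin-only (``mp``).  A doubly-negative class is
structurally unobservable — an undetected capillary is never counted — so
the three categories are exhaustive and the marginal positivity rates
satisfy ``f_contrast_pos + f_mp = 1`` and ``f_lectin_pos + f_pm = 1``
exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .phantoms import ClassificationCounts

__all__ = [
    "SamplingDesign",
    "PerfusionSummary",
    "systematic_random_positions",
    "sample_fields_of_view",
    "summarize_perfusion",
]


@dataclass
class SamplingDesign:
    """Stereological sampling plan for one muscle.

    Defaults mirror a standard design: 3 sections per muscle, 4 fields of
    view per section, systematically sampled from a row-major raster of
    candidate FOV positions over each section.
    """

    sections_per_muscle: int = 3
    fovs_per_section: int = 4
    candidates_per_section: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sections_per_muscle, self.fovs_per_section,
               self.candidates_per_section) < 1:
            raise ValueError("all design integers must be positive")
        if self.fovs_per_section > self.candidates_per_section:
            raise ValueError("fovs_per_section must not exceed candidate positions")


def systematic_random_positions(
    n_candidates: int, n_select: int, seed: int
) -> list[int]:
    """Select ``n_select`` of ``n_candidates`` indices systematically.

    With period ``T = n_candidates / n_select`` and a single random start
    ``u ~ Uniform[0, T)``, the selected indices are ``floor(u + k·T)`` for
    ``k = 0 .. n_select−1`` — all distinct, strictly increasing, and each
    index has inclusion probability exactly ``n_select / n_candidates``.
    """
    if not (1 <= n_select <= n_candidates):
        raise ValueError(
            f"need 1 <= n_select <= n_candidates, got {n_select}, {n_candidates}"
        )
    period = n_candidates / n_select
    u = np.random.default_rng(seed).uniform(0.0, period)
    idx = [int(math.floor(u + k * period)) for k in range(n_select)]
    assert idx[-1] < n_candidates and len(set(idx)) == n_select
    return idx


def sample_fields_of_view(design: SamplingDesign) -> dict[int, list[int]]:
    """Systematically sampled FOV indices per section.

    Each section gets an independent random start derived from the design
    seed; candidate positions are a row-major raster index 0..candidates−1.
    """
    rng = np.random.default_rng(design.seed)
    out: dict[int, list[int]] = {}
    for s in range(design.sections_per_muscle):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        out[s] = systematic_random_positions(
            design.candidates_per_section, design.fovs_per_section, sub_seed
        )
    return out


@dataclass
class PerfusionSummary:
    """Pooled and per-animal perfusion-efficiency fractions.

    Fractions are stored at full precision; ``to_report`` rounds category
    percentages to integers and marginals to one decimal for display.
    ``sd`` entries are sample standard deviations (n−1) across animal-level
    fractions, NaN when fewer than two animals contribute.
    """

    f_pp: float
    f_pm: float
    f_mp: float
    f_contrast_pos: float
    f_lectin_pos: float
    per_animal: pd.DataFrame
    mean: dict[str, float]
    sd: dict[str, float]
    n_total: int

    KEYS = ("f_pp", "f_pm", "f_mp", "f_contrast_pos", "f_lectin_pos")

    def to_report(self) -> dict:
        return {
            "n_capillaries": self.n_total,
            "pooled_percent": {
                "double_positive": round(100 * self.f_pp),
                "contrast_only": round(100 * self.f_pm),
                "lectin_only": round(100 * self.f_mp),
                "contrast_positive": round(100 * self.f_contrast_pos, 1),
                "lectin_positive": round(100 * self.f_lectin_pos, 1),
            },
            "per_animal_mean_percent": {k: 100 * v for k, v in self.mean.items()},
            "per_animal_sd_percent": {k: 100 * v for k, v in self.sd.items()},
            "raw": {k: getattr(self, k) for k in self.KEYS},
        }

    def write_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_report(), indent=2))
        return path


def summarize_perfusion(counts: ClassificationCounts) -> PerfusionSummary:
    """Summarize dual-label counts into perfusion-efficiency fractions.

    Pooled fractions sum all counts first (invariant to the section/FOV
    grouping); per-animal fractions are computed within each animal and
    then averaged (mean ± sample SD across animals).  Marginals are
    ``f_contrast_pos = f_pp + f_pm`` and ``f_lectin_pos = f_pp + f_mp``.
    Animals with zero counts are excluded from the per-animal statistics.
    """
    per_animal = counts.per_animal()
    totals = per_animal.sum(axis=1)
    if int(totals.sum()) == 0:
        raise ValueError("no capillaries counted")
    if (totals == 0).any():
        import warnings

        empty = totals.index[totals == 0].tolist()
        warnings.warn(f"animals with zero counts excluded: {empty}")
        per_animal = per_animal.loc[totals > 0]
        totals = totals[totals > 0]

    pooled = per_animal.sum(axis=0).to_numpy(float)
    n_total = int(pooled.sum())
    f_pp, f_pm, f_mp = pooled / n_total

    fr = per_animal.div(totals, axis=0)
    fr = fr.rename(columns={"n_pp": "f_pp", "n_pm": "f_pm", "n_mp": "f_mp"})
    fr["f_contrast_pos"] = fr["f_pp"] + fr["f_pm"]
    fr["f_lectin_pos"] = fr["f_pp"] + fr["f_mp"]
    mean = {k: float(fr[k].mean()) for k in PerfusionSummary.KEYS}
    sd = {
        k: float(fr[k].std(ddof=1)) if len(fr) > 1 else float("nan")
        for k in PerfusionSummary.KEYS
    }
    return PerfusionSummary(
        f_pp=float(f_pp),
        f_pm=float(f_pm),
        f_mp=float(f_mp),
        f_contrast_pos=float(f_pp + f_pm),
        f_lectin_pos=float(f_pp + f_mp),
        per_animal=fr,
        mean=mean,
        sd=sd,
        n_total=n_total,
    )
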