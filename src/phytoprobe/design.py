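"""Split-plot randomization and response-surface fitting.

Chambers act as whole-plot units receiving environmental treatment
combinations; pots inside each chamber are split-plot units receiving
genotypes.  Replication across runs uses fresh randomizations drawn from
a seeded stream split on the run id.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignLayout",
    "ResponseSurfaceFit",
    "GenotypeFit",
    "enumerate_combinations",
    "assign_splitplot",
    "new_replication",
    "fit_response_surface",
]


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class FactorSpec:
    name: str
    levels: tuple

    def __post_init__(self) -> None:
        if len(self.levels) < 2 or len(set(self.levels)) != len(self.levels):
            raise DesignError(
                f"factor {self.name!r} needs >= 2 distinct levels")
        object.__setattr__(self, "levels", tuple(self.levels))


def enumerate_combinations(factors: Sequence[FactorSpec]) -> list[dict]:
    """Full Cartesian product of factor levels, lexicographic in factor order."""
    if not factors:
        raise DesignError("at least one factor required")
    names = [f.name for f in factors]
    return [
        dict(zip(names, combo))
        for combo in itertools.product(*(f.levels for f in factors))
    ]


@dataclass(frozen=True)
class DesignLayout:
    """One randomized run of a split-plot experiment."""

    run_id: int
    chamber_assignments: dict      # chamber -> treatment combination
    pot_assignments: dict          # chamber -> {pot position -> genotype}
    seed: int
    chambers: tuple = ()
    genotypes: tuple = ()
    combinations: tuple = ()
    pots_per_chamber: int = 0

    def units(self) -> list[tuple]:
        """All (chamber, pot) split-plot units."""
        return [
            (ch, pot)
            for ch, pots in self.pot_assignments.items()
            for pot in pots
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ch in self.chamber_assignments:
            combo = self.chamber_assignments[ch]
            for pot, geno in self.pot_assignments[ch].items():
                row = {"run": self.run_id, "chamber": ch, "pot": pot,
                       "genotype": geno}
                row.update({f"factor_{k}": v for k, v in combo.items()})
                rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "schema_version": 1,
            "run_id": self.run_id,
            "seed": self.seed,
            "chamber_assignments": {
                str(ch): combo for ch, combo in self.chamber_assignments.items()
            },
            "pot_assignments": {
                str(ch): {str(p): g for p, g in pots.items()}
                for ch, pots in self.pot_assignments.items()
            },
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


def _rng_for_run(seed: int, run_id: int) -> np.random.Generator:
    # Stream split on (seed, run_id): replications with the same base seed
    # still draw independent permutations.
    return np.random.default_rng(np.random.SeedSequence([seed, run_id]))


def assign_splitplot(
    chambers: Sequence,
    combinations: Sequence[Mapping],
    genotypes: Sequence,
    pots_per_chamber: int,
    seed: int,
    run_id: int = 1,
) -> DesignLayout:
    """Randomize treatment combinations to chambers and genotypes to pots.

    Combinations are assigned by a uniform random permutation; when there
    are fewer combinations than chambers each combination is repeated a
    balanced number of times (chambers must divide evenly).  Genotypes
    are independently permuted within each chamber.  Deterministic for a
    fixed ``(seed, run_id)``.
    """
    chambers = list(chambers)
    combinations = list(combinations)
    genotypes = list(genotypes)
    if not chambers or not combinations or not genotypes:
        raise DesignError("chambers, combinations and genotypes must be nonempty")
    if len(combinations) > len(chambers):
        raise DesignError(
            f"{len(combinations)} combinations exceed {len(chambers)} chambers; "
            "split the experiment into blocked runs (incomplete block design, "
            "multiple runs as blocks)"
        )
    if len(chambers) % len(combinations) != 0:
        raise DesignError(
            "chamber count must be a multiple of the combination count "
            "for balanced whole-plot repetition"
        )
    if len(genotypes) > pots_per_chamber:
        raise DesignError("more genotypes than pots per chamber")

    rng = _rng_for_run(seed, run_id)
    reps = len(chambers) // len(combinations)
    pool = combinations * reps
    order = rng.permutation(len(pool))
    chamber_assignments = {
        ch: dict(pool[i]) for ch, i in zip(chambers, order)
    }
    pot_assignments = {}
    for ch in chambers:
        perm = rng.permutation(pots_per_chamber)[: len(genotypes)]
        pot_assignments[ch] = {
            int(pos): genotypes[g] for g, pos in enumerate(sorted(perm))
        }
    return DesignLayout(
        run_id=run_id,
        chamber_assignments=chamber_assignments,
        pot_assignments=pot_assignments,
        seed=seed,
        chambers=tuple(chambers),
        genotypes=tuple(genotypes),
        combinations=tuple(tuple(sorted(c.items())) for c in combinations),
        pots_per_chamber=pots_per_chamber,
    )


def new_replication(layout: DesignLayout, seed: int | None = None) -> DesignLayout:
    """Fresh randomization for the next run of the same experiment.

    Keeps chambers, genotypes and combinations; increments ``run_id`` and
    redraws both permutations from the (seed, run_id) stream, so reusing
    the original seed still yields a different layout.
    """
    combos = [dict(c) for c in layout.combinations]
    return assign_splitplot(
        chambers=layout.chambers,
        combinations=combos,
        genotypes=layout.genotypes,
        pots_per_chamber=layout.pots_per_chamber,
        seed=layout.seed if seed is None else seed,
        run_id=layout.run_id + 1,
    )


# --------------------------------------------------------------------------
# Response surface
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeFit:
    genotype: object
    coefficients: tuple[float, float, float]   # intercept, linear, quadratic
    std_errors: tuple[float, float, float]
    optimum: float
    fitted: bool = True
    note: str = ""


@dataclass(frozen=True)
class ResponseSurfaceFit:
    fits: dict
    level_range: tuple[float, float]

    def optimum(self, genotype) -> float:
        return self.fits[genotype].optimum


def fit_response_surface(
    data: pd.DataFrame | Sequence[Mapping],
    level_range: tuple[float, float],
    genotype_col: str = "genotype",
    level_col: str = "level",
    response_col: str = "response",
    curvature_tol: float = 1e-12,
) -> ResponseSurfaceFit:
    """Per-genotype quadratic response fit with clipped optimum.

    Least squares of ``response ~ 1 + level + level^2`` per genotype.
    The optimum is the vertex ``-b / (2 c)`` when the curvature is
    negative and the vertex lies within ``level_range``; otherwise the
    range endpoint with the higher fitted value.  Genotypes with fewer
    than 3 distinct levels are flagged, not fitted.
    """
    df = pd.DataFrame(data)
    lo, hi = level_range
    if not lo < hi:
        raise DesignError("level_range must be a nonempty interval")
    fits: dict = {}
    for geno, grp in df.groupby(genotype_col, sort=False):
        t = grp[level_col].to_numpy(dtype=float)
        y = grp[response_col].to_numpy(dtype=float)
        if len(np.unique(t)) < 3:
            fits[geno] = GenotypeFit(
                genotype=geno, coefficients=(np.nan,) * 3,
                std_errors=(np.nan,) * 3, optimum=np.nan,
                fitted=False, note="fewer than 3 distinct levels",
            )
            continue
        X = np.column_stack([np.ones_like(t), t, t * t])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        dof = len(y) - 3
        if dof > 0:
            sigma2 = float(resid @ resid) / dof
            cov = sigma2 * np.linalg.inv(X.T @ X)
            se = tuple(float(s) for s in np.sqrt(np.diag(cov)))
        else:
            se = (np.nan, np.nan, np.nan)
        a, b, c = (float(v) for v in coef)
        if c < -curvature_tol:
            vertex = -b / (2.0 * c)
            if lo <= vertex <= hi:
                opt = vertex
            else:
                opt = _better_endpoint(a, b, c, lo, hi)
        else:
            opt = _better_endpoint(a, b, c, lo, hi)
        fits[geno] = GenotypeFit(
            genotype=geno, coefficients=(a, b, c), std_errors=se, optimum=opt,
        )
    return ResponseSurfaceFit(fits=fits, level_range=(lo, hi))


def _better_endpoint(a: float, b: float, c: float,
                     lo: float, hi: float) -> float:
    f = lambda t: a + b * t + c * t * t
    return lo if f(lo) > f(hi) else hi
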