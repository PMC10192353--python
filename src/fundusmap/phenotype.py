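"""Fundus-spot phenotypes: a genotype-dependent count model and the 0-8 scale.

The scoring scale grades each eye 0-4 from the number and quadrant coverage
of white/yellow fundus spots: no spots scores 0; 1-10 spots score 1; spots
equivalent to one fundus quadrant score 2; two to three quadrants score 3;
all four quadrants score 4.  The two eye scores are summed into a per-mouse
score of 0-8 (nine achievable values).

The synthetic count model draws per-eye spot totals from a negative binomial
whose mean depends on genotype at an optional causal site, then splits the
total uniformly over the four quadrants.  The scale operations themselves
(`score_eye`, `score_mouse`, `phenotype_table`) are model-free and apply
equally to real per-quadrant counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from fundusmap.pedigree import GenotypeCall, Pedigree

EYES = ("OD", "OS")
QUADRANTS = ("superior", "inferior", "nasal", "temporal")

#: susceptibility weight of each genotype code (REF, HET, VAR) per inheritance
_SUSCEPTIBILITY = {
    "recessive": (0.0, 0.0, 1.0),
    "additive": (0.0, 0.5, 1.0),
    "dominant": (0.0, 1.0, 1.0),
}


@dataclass(frozen=True)
class FundusExam:
    """Per-eye spot counts in the four fundus quadrants."""

    mouse_id: str
    eye: str
    quadrant_counts: tuple[int, int, int, int]
    age_months: float = 0.0

    def __post_init__(self) -> None:
        if self.eye not in EYES:
            raise ValueError(f"eye must be one of {EYES}, got {self.eye!r}")
        if len(self.quadrant_counts) != 4:
            raise ValueError("exactly 4 quadrant counts required")
        for c in self.quadrant_counts:
            if int(c) != c or c < 0:
                raise ValueError(f"quadrant counts must be integers >= 0, got {c!r}")
        if self.age_months < 0:
            raise ValueError("age_months must be non-negative")

    @property
    def total(self) -> int:
        return int(sum(self.quadrant_counts))


@dataclass(frozen=True)
class PhenotypeModel:
    """Generative model for per-eye spot counts.

    Expected spots per eye are
    ``lambda = baseline_mean + g * effect_size + age_slope * age_months``
    where ``g`` is the susceptibility weight of the mouse's genotype at the
    causal site under ``inheritance`` (recessive: REF 0, HET 0, VAR 1;
    additive: 0, 0.5, 1; dominant: 0, 1, 1).  Counts are negative binomial
    with that mean and shape ``dispersion`` (variance lambda + lambda^2 /
    dispersion), so larger ``dispersion`` approaches Poisson.
    """

    baseline_mean: float = 1.0
    effect_size: float = 40.0
    inheritance: str = "recessive"
    age_slope: float = 0.0
    dispersion: float = 10.0

    def __post_init__(self) -> None:
        if self.baseline_mean < 0 or self.effect_size < 0:
            raise ValueError("baseline_mean and effect_size must be non-negative")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.inheritance not in _SUSCEPTIBILITY:
            raise ValueError(
                f"inheritance must be one of {tuple(_SUSCEPTIBILITY)}, "
                f"got {self.inheritance!r}"
            )

    def susceptibility(self, genotype_code: int) -> float:
        return _SUSCEPTIBILITY[self.inheritance][genotype_code]


def _draw_counts(lam: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Negative binomial draws with mean lam and shape parameter dispersion."""
    lam = np.asarray(lam, dtype=float)
    out = np.zeros(lam.shape, dtype=np.int64)
    pos = lam > 0
    if np.any(pos):
        p = dispersion / (dispersion + lam[pos])
        out[pos] = rng.negative_binomial(dispersion, p)
    return out


def simulate_exams(
    pedigree: Pedigree,
    causal_site: str | None,
    model: PhenotypeModel,
    rng: np.random.Generator | None = None,
) -> list[FundusExam]:
    """Simulate both eyes of every G3 mouse in the pedigree.

    With ``causal_site=None`` (or ``effect_size=0``) all mice share the
    baseline count distribution: a pure-noise null screen.  The two eyes are
    sampled independently given genotype.
    """
    if rng is None:
        rng = np.random.default_rng()
    g3 = pedigree.mice_of("G3")
    if causal_site is not None:
        if causal_site not in pedigree.site_ids:
            raise ValueError(f"causal_site {causal_site!r} not in pedigree")
        codes = pedigree.genotypes_at(causal_site, "G3")
    else:
        codes = np.zeros(len(g3), dtype=np.int8)

    g = np.array([model.susceptibility(int(c)) for c in codes])
    ages = np.array([m.age_months for m in g3])
    lam = model.baseline_mean + g * model.effect_size + model.age_slope * ages
    lam = np.clip(lam, 0.0, None)

    exams: list[FundusExam] = []
    for eye in EYES:
        totals = _draw_counts(lam, model.dispersion, rng)
        for mouse, age, total in zip(g3, ages, totals):
            quad = rng.multinomial(int(total), [0.25] * 4)
            exams.append(
                FundusExam(
                    mouse_id=mouse.mouse_id,
                    eye=eye,
                    quadrant_counts=tuple(int(q) for q in quad),
                    age_months=float(age),
                )
            )
    # interleave per mouse (OD then OS) for readability
    exams.sort(key=lambda e: (e.mouse_id, e.eye))
    return exams


def score_eye(exam: FundusExam, quadrant_involvement_threshold: int = 3) -> int:
    """Grade one eye 0-4 on the semiquantitative fundus-spot scale.

    No spots scores 0 and a total of 1-10 spots scores 1.  Above 10 spots
    the grade reflects quadrant coverage: a quadrant counts as involved when
    it holds at least ``quadrant_involvement_threshold`` spots, and
    involvement of at most one quadrant scores 2, two or three quadrants
    score 3, and all four score 4.
    """
    if quadrant_involvement_threshold < 1:
        raise ValueError("quadrant_involvement_threshold must be >= 1")
    counts = exam.quadrant_counts
    total = exam.total
    if total == 0:
        return 0
    if total <= 10:
        return 1
    involved = sum(1 for c in counts if c >= quadrant_involvement_threshold)
    if involved <= 1:
        return 2
    if involved <= 3:
        return 3
    return 4


def score_mouse(od: int, os: int) -> int:
    """Sum the two per-eye grades into the 0-8 per-mouse score."""
    for v in (od, os):
        if int(v) != v or not 0 <= v <= 4:
            raise ValueError(f"eye scores must be integers in 0..4, got {v!r}")
    return int(od) + int(os)


def phenotype_table(
    exams: list[FundusExam], quadrant_involvement_threshold: int = 3
) -> pd.DataFrame:
    """Per-mouse score table from per-eye exams.

    Every mouse must contribute exactly two exams (one OD, one OS); the
    result has columns mouse_id, age_months, od_score, os_score, mouse_score.
    """
    by_mouse: dict[str, dict[str, FundusExam]] = {}
    for exam in exams:
        by_mouse.setdefault(exam.mouse_id, {})
        if exam.eye in by_mouse[exam.mouse_id]:
            raise ValueError(f"mouse {exam.mouse_id!r} has duplicate {exam.eye} exams")
        by_mouse[exam.mouse_id][exam.eye] = exam

    records = []
    for mouse_id, eyes in by_mouse.items():
        if set(eyes) != set(EYES):
            raise ValueError(
                f"mouse {mouse_id!r} must have exactly one OD and one OS exam, "
                f"found {sorted(eyes)}"
            )
        od = score_eye(eyes["OD"], quadrant_involvement_threshold)
        os_ = score_eye(eyes["OS"], quadrant_involvement_threshold)
        records.append(
            {
                "mouse_id": mouse_id,
                "age_months": eyes["OD"].age_months,
                "od_score": od,
                "os_score": os_,
                "mouse_score": score_mouse(od, os_),
            }
        )
    return pd.DataFrame.from_records(records)


def exam_table(exams: list[FundusExam]) -> pd.DataFrame:
    """Raw-count table: mouse_id, eye, one column per quadrant, age_months."""
    return pd.DataFrame.from_records(
        [
            {
                "mouse_id": e.mouse_id,
                "eye": e.eye,
                "q_superior": e.quadrant_counts[0],
                "q_inferior": e.quadrant_counts[1],
                "q_nasal": e.quadrant_counts[2],
                "q_temporal": e.quadrant_counts[3],
                "age_months": e.age_months,
            }
            for e in exams
        ]
    )
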