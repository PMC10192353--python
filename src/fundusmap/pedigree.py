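"""Synthetic ENU pedigrees: mutation sets, breeding design, Mendelian genotypes.

The screen's breeding design: a mutagenized G0 male sires G1 males that each
carry a private set of heterozygous point mutations.  A G1 male is crossed to
wild-type females; G2 daughters (each HET at any given site with probability
1/2, never homozygous variant) are backcrossed to the G1 sire, and their G3
pups are the screened generation.  At any one site the marginal G3 genotype
probabilities are therefore REF 3/8, HET 1/2, VAR 1/8, and conditional on a
HET dam the classic 1:2:1 backcross-intercross ratio holds.

Genotypes are stored internally as a compact integer matrix (0=REF, 1=HET,
2=VAR); the string vocabulary only appears at the table/file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GENOTYPE_CALLS = ("REF", "HET", "VAR")

EFFECT_CLASSES = (
    "probably_null",
    "probably_damaging",
    "possibly_damaging",
    "probably_benign",
)

#: Default mix of predicted-effect classes for ENU coding/splice mutations.
#: Most ENU point mutations are missense of uncertain impact; outright null
#: (nonsense/splice) alleles are the minority.
DEFAULT_EFFECT_CLASS_PROBS = (0.10, 0.25, 0.25, 0.40)

#: Mouse autosome lengths (Mb, GRCm39 rounded); used to draw site positions.
_CHROM_LENGTH_MB = {
    "1": 195, "2": 182, "3": 160, "4": 157, "5": 152, "6": 150, "7": 145,
    "8": 130, "9": 124, "10": 130, "11": 122, "12": 120, "13": 121,
    "14": 125, "15": 104, "16": 98, "17": 95, "18": 91, "19": 61,
}

GENERATIONS = ("G1", "G2", "G3")


class GenotypeCall:
    """The three-state genotype vocabulary at one induced mutation site."""

    REF = "REF"
    HET = "HET"
    VAR = "VAR"

    #: integer codes used by the internal genotype matrix
    CODES: Mapping[str, int] = {"REF": 0, "HET": 1, "VAR": 2}

    @staticmethod
    def validate(value: str) -> str:
        if value not in GENOTYPE_CALLS:
            raise ValueError(
                f"invalid genotype call {value!r}; expected one of {GENOTYPE_CALLS}"
            )
        return value


@dataclass(frozen=True)
class MutationSite:
    """One ENU-induced coding/splice variant segregating in a pedigree."""

    site_id: str
    chromosome: str
    position_bp: int
    gene: str
    effect_class: str

    def __post_init__(self) -> None:
        if self.position_bp <= 0:
            raise ValueError(f"position_bp must be positive, got {self.position_bp}")
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(
                f"effect_class {self.effect_class!r} not in {EFFECT_CLASSES}"
            )


@dataclass
class MouseRecord:
    """A pedigree member with its generation, parents and genotype calls."""

    mouse_id: str
    generation: str
    sex: str
    sire_id: str | None
    dam_id: str | None
    age_months: float
    genotypes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.generation not in GENERATIONS:
            raise ValueError(f"unknown generation {self.generation!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.age_months < 0:
            raise ValueError("age_months must be non-negative")


@dataclass
class Pedigree:
    """A full G1 -> G2 -> G3 family with genotypes at every site.

    ``genotype_matrix`` holds the integer-coded calls (mice x sites, rows in
    ``mice`` order, columns in ``sites`` order); ``MouseRecord.genotypes``
    exposes the same information as string calls keyed by site id.
    """

    sites: list[MutationSite]
    mice: list[MouseRecord]
    seed: int
    genotype_matrix: np.ndarray  # int8, shape (n_mice, n_sites)

    def __post_init__(self) -> None:
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("site_ids must be unique within a pedigree")
        g1 = [m for m in self.mice if m.generation == "G1"]
        if len(g1) != 1:
            raise ValueError(f"pedigree must have exactly one G1 sire, found {len(g1)}")

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    @property
    def g1_sire(self) -> MouseRecord:
        return next(m for m in self.mice if m.generation == "G1")

    def mice_of(self, generation: str) -> list[MouseRecord]:
        if generation not in GENERATIONS:
            raise ValueError(f"unknown generation {generation!r}")
        return [m for m in self.mice if m.generation == generation]

    def genotypes_at(self, site_id: str, generation: str = "G3") -> np.ndarray:
        """Integer-coded calls (0/1/2) at one site for one generation."""
        try:
            j = self.site_ids.index(site_id)
        except ValueError:
            raise KeyError(f"unknown site_id {site_id!r}") from None
        rows = [i for i, m in enumerate(self.mice) if m.generation == generation]
        return self.genotype_matrix[rows, j]


def draw_mutation_set(
    n_sites: int,
    effect_class_probs: Sequence[float] = DEFAULT_EFFECT_CLASS_PROBS,
    rng: np.random.Generator | None = None,
) -> list[MutationSite]:
    """Draw a G1 founder's heterozygous mutation set.

    Sites are placed uniformly at random on the 19 mouse autosomes
    (chromosome chosen with probability proportional to its length, position
    uniform along the chromosome) and assigned a predicted-effect class
    i.i.d. from ``effect_class_probs`` over
    (probably_null, probably_damaging, possibly_damaging, probably_benign).
    """
    if n_sites < 0:
        raise ValueError(f"n_sites must be non-negative, got {n_sites}")
    probs = np.asarray(effect_class_probs, dtype=float)
    if probs.shape != (4,):
        raise ValueError("effect_class_probs must have exactly 4 entries")
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("effect_class_probs must be non-negative and sum to 1")
    if rng is None:
        rng = np.random.default_rng()

    chroms = list(_CHROM_LENGTH_MB)
    lengths = np.array([_CHROM_LENGTH_MB[c] for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n_sites, p=lengths / lengths.sum())
    class_idx = rng.choice(4, size=n_sites, p=probs)

    sites = []
    for k in range(n_sites):
        chrom = chroms[chrom_idx[k]]
        pos = int(rng.integers(1, _CHROM_LENGTH_MB[chrom] * 1_000_000 + 1))
        sites.append(
            MutationSite(
                site_id=f"site{k:03d}",
                chromosome=chrom,
                position_bp=pos,
                gene=f"gene{k:03d}",
                effect_class=EFFECT_CLASSES[class_idx[k]],
            )
        )
    return sites


def breed_pedigree(
    sites: Sequence[MutationSite],
    n_g2_dams: int = 5,
    n_g3_per_dam: int = 8,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    g3_age_months: tuple[float, float] = (4.0, 6.0),
) -> Pedigree:
    """Breed a G1 sire through G2 dams to the screened G3 generation.

    The G1 sire is HET at every site.  Each G2 dam (bred from the sire and a
    wild-type female) is independently HET at each site with probability 1/2
    and never VAR.  Each G3 pup receives one allele from the sire (variant
    with probability 1/2 at every site) and one from its dam (variant with
    probability 1/2 where the dam is HET, never otherwise); two variant
    alleles make VAR, one makes HET.

    G3 screening ages are drawn uniformly over ``g3_age_months`` (the screen
    photographs G3 mice at 4-6 months).
    """
    if len(sites) == 0:
        raise ValueError("at least one mutation site is required")
    if n_g2_dams < 1 or n_g3_per_dam < 1:
        raise ValueError("need at least one G2 dam and one G3 pup per dam")
    if rng is None:
        rng = np.random.default_rng(seed)
    if seed is None:
        seed = -1  # unknown entropy; pedigree still self-consistent

    n_sites = len(sites)
    n_g3 = n_g2_dams * n_g3_per_dam

    # dam HET indicator, (dams x sites)
    dam_het = rng.integers(0, 2, size=(n_g2_dams, n_sites), dtype=np.int8)
    # transmissions: sire always HET -> variant allele w.p. 1/2
    sire_allele = rng.integers(0, 2, size=(n_g3, n_sites), dtype=np.int8)
    dam_coin = rng.integers(0, 2, size=(n_g3, n_sites), dtype=np.int8)
    dam_of_pup = np.repeat(np.arange(n_g2_dams), n_g3_per_dam)
    dam_allele = dam_coin * dam_het[dam_of_pup, :]
    g3_geno = sire_allele + dam_allele  # 0/1/2 counts of variant alleles

    ages_g3 = rng.uniform(g3_age_months[0], g3_age_months[1], size=n_g3)
    sexes_g3 = rng.choice(["M", "F"], size=n_g3)

    sire_id = "G1-sire"
    site_ids = [s.site_id for s in sites]

    mice: list[MouseRecord] = []
    rows: list[np.ndarray] = []

    mice.append(
        MouseRecord(sire_id, "G1", "M", None, None, age_months=12.0)
    )
    rows.append(np.ones(n_sites, dtype=np.int8))  # HET everywhere

    dam_ids = [f"G2-dam{d:02d}" for d in range(n_g2_dams)]
    for d, dam_id in enumerate(dam_ids):
        mice.append(
            MouseRecord(dam_id, "G2", "F", sire_id, None, age_months=10.0)
        )
        rows.append(dam_het[d])

    for k in range(n_g3):
        mice.append(
            MouseRecord(
                f"G3-{k:03d}",
                "G3",
                str(sexes_g3[k]),
                sire_id,
                dam_ids[dam_of_pup[k]],
                age_months=float(ages_g3[k]),
            )
        )
        rows.append(g3_geno[k])

    matrix = np.vstack(rows).astype(np.int8)
    inv = {v: k for k, v in GenotypeCall.CODES.items()}
    for mouse, row in zip(mice, matrix):
        mouse.genotypes = {sid: inv[int(c)] for sid, c in zip(site_ids, row)}

    return Pedigree(sites=list(sites), mice=mice, seed=int(seed), genotype_matrix=matrix)


def genotype_table(
    pedigree: Pedigree, generation_filter: str | None = None
) -> pd.DataFrame:
    """Rectangular genotype table: one row per mouse, one column per site.

    Leading columns are mouse_id, generation, sex and dam_id; the remaining
    columns are string calls (REF/HET/VAR), one per site, with no missing
    cells.  ``generation_filter`` restricts rows to one generation.
    """
    if generation_filter is not None and generation_filter not in GENERATIONS:
        raise ValueError(f"unknown generation label {generation_filter!r}")
    inv = {v: k for k, v in GenotypeCall.CODES.items()}
    records = []
    for i, mouse in enumerate(pedigree.mice):
        if generation_filter and mouse.generation != generation_filter:
            continue
        rec = {
            "mouse_id": mouse.mouse_id,
            "generation": mouse.generation,
            "sex": mouse.sex,
            "dam_id": mouse.dam_id if mouse.dam_id is not None else "NA",
        }
        for j, sid in enumerate(pedigree.site_ids):
            rec[sid] = inv[int(pedigree.genotype_matrix[i, j])]
        records.append(rec)
    return pd.DataFrame.from_records(records)


def mutation_table(pedigree: Pedigree) -> pd.DataFrame:
    """Site annotation table: site_id, chromosome, position_bp, gene, effect_class."""
    return pd.DataFrame.from_records(
        [
            {
                "site_id": s.site_id,
                "chromosome": s.chromosome,
                "position_bp": s.position_bp,
                "gene": s.gene,
                "effect_class": s.effect_class,
            }
            for s in pedigree.sites
        ]
    )
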