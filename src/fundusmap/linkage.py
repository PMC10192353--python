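"""Automated meiotic mapping: single-locus association scans and candidate calling.

For every mutation site in a pedigree the phenotype (the continuous 0-8
fundus-spot score, or any quantitative trait) is regressed on a numeric
genotype encoding under up to three inheritance models:

    recessive     REF 0, HET 0, VAR 1
    semidominant  REF 0, HET 1, VAR 2
    dominant      REF 0, HET 1, VAR 1

The slope's two-sided t test (n-2 df) gives a per-site, per-model p-value;
the pedigree-wide scan is summarized as a Manhattan table of -log10 p
against genomic position.  A site is a candidate when (1) its best p-value
clears the 0.05 Bonferroni threshold and (2) its peak stands at least 3 logs
above the second-highest peak in the pedigree (peak-dominance rule).

Dichotomized (affected / unaffected) traits use an exact 2x2 test instead of
the regression.  A simulation driver estimates detection power and the
family-wise false-candidate rate over replicate pedigrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from fundusmap.pedigree import GenotypeCall, breed_pedigree, draw_mutation_set, genotype_table, mutation_table
from fundusmap.phenotype import PhenotypeModel, phenotype_table, simulate_exams

MODELS = ("recessive", "semidominant", "dominant")

_ENCODINGS: Mapping[str, tuple[float, float, float]] = {
    "recessive": (0.0, 0.0, 1.0),
    "semidominant": (0.0, 1.0, 2.0),
    "dominant": (0.0, 1.0, 1.0),
}

#: floor for p-values so -log10 p stays finite on perfect separations
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class LinkageResult:
    """One site x one model regression outcome."""

    site_id: str
    model: str
    n: int
    beta0: float
    beta1: float
    stat: float
    df: int
    p: float
    neglog10p: float
    status: str  # "ok" or "degenerate"


@dataclass(frozen=True)
class CandidateCall:
    """Candidate decision for the lead peak of one scan."""

    site_id: str
    above_threshold: bool
    margin_logs: float
    is_candidate: bool


@dataclass
class PowerReport:
    """Summary of a replicate-pedigree power / type-I-error simulation."""

    n_reps: int
    power: float
    familywise_fp_rate: float
    per_model_power: dict[str, float]
    encoding_mode: str
    seed: int
    pvalues: dict[str, np.ndarray] = field(default_factory=dict)


def _as_codes(calls: Sequence) -> np.ndarray:
    """Genotype calls (strings or 0/1/2 codes) -> int array."""
    arr = np.asarray(calls)
    if arr.size == 0:
        raise ValueError("genotype vector must be non-empty")
    if arr.dtype.kind in "iu":
        codes = arr.astype(np.int64)
        if codes.min() < 0 or codes.max() > 2:
            raise ValueError("integer genotype codes must be 0 (REF), 1 (HET) or 2 (VAR)")
        return codes
    codes = np.empty(arr.shape, dtype=np.int64)
    for i, v in enumerate(arr.ravel()):
        if v not in GenotypeCall.CODES:
            raise ValueError(f"unknown genotype call {v!r}")
        codes.ravel()[i] = GenotypeCall.CODES[v]
    return codes


def encode_genotypes(calls: Sequence, model: str) -> np.ndarray:
    """Numeric genotype encoding under one inheritance model."""
    if model not in _ENCODINGS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    codes = _as_codes(calls)
    lut = np.array(_ENCODINGS[model])
    return lut[codes]


def single_locus_test(phenotype: Sequence[float], calls: Sequence, model: str) -> LinkageResult:
    """OLS of phenotype on the encoded genotype at one site.

    Two-sided p from the t distribution with n-2 df on the slope.  When the
    encoded genotypes or the phenotype have zero variance the fit is
    reported as degenerate (stat and p are NaN) rather than forced to a
    p of 1.
    """
    y = np.asarray(phenotype, dtype=float)
    codes = _as_codes(calls)
    if y.shape[0] != codes.shape[0]:
        raise ValueError(f"length mismatch: {y.shape[0]} phenotypes vs {codes.shape[0]} genotypes")
    n = y.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 mice, got {n}")
    x = encode_genotypes(codes, model)

    sxx = float(np.sum((x - x.mean()) ** 2))
    syy = float(np.sum((y - y.mean()) ** 2))
    if sxx == 0.0 or syy == 0.0:
        return LinkageResult(
            site_id="", model=model, n=n, beta0=float("nan"), beta1=float("nan"),
            stat=float("nan"), df=n - 2, p=float("nan"), neglog10p=float("nan"),
            status="degenerate",
        )
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    beta1 = sxy / sxx
    beta0 = float(y.mean() - beta1 * x.mean())
    sse = syy - beta1 * sxy
    sse = max(sse, 0.0)
    df = n - 2
    sigma2 = sse / df
    if sigma2 == 0.0:
        t = math.inf if beta1 > 0 else -math.inf
        p = _P_FLOOR
    else:
        t = beta1 / math.sqrt(sigma2 / sxx)
        p = float(2.0 * stats.t.sf(abs(t), df))
        p = min(max(p, _P_FLOOR), 1.0)
    return LinkageResult(
        site_id="", model=model, n=n, beta0=beta0, beta1=beta1, stat=t,
        df=df, p=p, neglog10p=-math.log10(p), status="ok",
    )


def _ols_scan(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized slope t tests: y (n,), x (n, k) -> (t, p), NaN where degenerate."""
    n = y.shape[0]
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sxx = np.sum(xc * xc, axis=0)
    syy = float(np.sum(yc * yc))
    sxy = yc @ xc
    with np.errstate(divide="ignore", invalid="ignore"):
        beta1 = sxy / sxx
        sse = np.maximum(syy - beta1 * sxy, 0.0)
        sigma2 = sse / (n - 2)
        tstat = beta1 / np.sqrt(sigma2 / sxx)
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    p = np.clip(p, _P_FLOOR, 1.0)
    degenerate = (sxx == 0.0) | (syy == 0.0)
    tstat = np.where(degenerate, np.nan, tstat)
    p = np.where(degenerate, np.nan, p)
    # perfect fits: sigma2 == 0 but not degenerate
    perfect = (~degenerate) & (sigma2 == 0.0)
    with np.errstate(invalid="ignore"):
        tstat = np.where(perfect, np.inf * np.sign(beta1), tstat)
    p = np.where(perfect, _P_FLOOR, p)
    return tstat, p


def ordinal_association_test(affected: Sequence[bool], calls: Sequence, model: str):
    """Exact test for a dichotomized trait against genotype susceptibility.

    The encoding is collapsed to susceptible (encoded value > 0) versus
    non-susceptible, cross-tabulated against affected status, and tested
    with the two-sided exact hypergeometric (Fisher) test on the 2x2 table.
    Returns a LinkageResult-like record; a genotype arm with no mice yields
    a degenerate status.
    """
    aff = np.asarray(affected, dtype=bool)
    x = encode_genotypes(calls, model) > 0
    if aff.shape[0] != x.shape[0]:
        raise ValueError("length mismatch between affected vector and genotype calls")
    n = aff.shape[0]
    a = int(np.sum(aff & x))
    b = int(np.sum(aff & ~x))
    c = int(np.sum(~aff & x))
    d = int(np.sum(~aff & ~x))
    if (a + c) == 0 or (b + d) == 0:  # one genotype arm empty
        return LinkageResult(
            site_id="", model=model, n=n, beta0=float("nan"), beta1=float("nan"),
            stat=float("nan"), df=n - 2, p=float("nan"), neglog10p=float("nan"),
            status="degenerate",
        )
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    p = min(max(float(p), _P_FLOOR), 1.0)
    return LinkageResult(
        site_id="", model=model, n=n, beta0=float("nan"), beta1=float("nan"),
        stat=float("nan"), df=n - 2, p=p, neglog10p=-math.log10(p), status="ok",
    )


def bonferroni_threshold(n_sites: int, n_models: int = 3, alpha: float = 0.05) -> float:
    """Family-wise 0.05 threshold: alpha / (number of sites x models tested)."""
    if n_sites < 1 or n_models < 1:
        raise ValueError("n_sites and n_models must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return alpha / (n_sites * n_models)


def _genotype_codes_from_table(genotypes: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    meta_cols = [c for c in ("mouse_id", "generation", "sex", "dam_id") if c in genotypes.columns]
    site_cols = [c for c in genotypes.columns if c not in meta_cols]
    lut = GenotypeCall.CODES
    codes = np.empty((len(genotypes), len(site_cols)), dtype=np.int64)
    for j, col in enumerate(site_cols):
        vals = genotypes[col].to_numpy()
        for i, v in enumerate(vals):
            if v not in lut:
                raise ValueError(f"unknown genotype call {v!r} at site {col!r}")
            codes[i, j] = lut[v]
    return site_cols, codes


def scan_pedigree(
    phenotypes: pd.DataFrame,
    genotypes: pd.DataFrame,
    models: Iterable[str] = MODELS,
    sites: pd.DataFrame | None = None,
    response: str = "mouse_score",
) -> pd.DataFrame:
    """Scan every site under every requested model; return the Manhattan table.

    ``phenotypes`` needs columns mouse_id and ``response``; ``genotypes`` is
    the rectangular genotype table (one column per site).  ``sites`` is an
    optional annotation table (site_id, chromosome, position_bp, gene)
    merged into the output.  Each row carries per-model p-values, the best
    (minimum) non-degenerate p with its model and -log10, the VAR-mouse
    count, and a status flag for sites degenerate under every model.
    """
    models = list(models)
    for m in models:
        if m not in MODELS:
            raise ValueError(f"unknown model {m!r}")
    if not models:
        raise ValueError("at least one model required")

    pheno = phenotypes.set_index("mouse_id")
    geno = genotypes.set_index("mouse_id")
    missing = sorted(set(pheno.index) - set(geno.index))
    if missing:
        raise ValueError(f"phenotyped mice missing from genotype table: {missing}")
    geno = geno.loc[pheno.index].reset_index()

    y = pheno[response].to_numpy(dtype=float)
    site_cols, codes = _genotype_codes_from_table(geno)

    rows: dict[str, np.ndarray] = {}
    for m in models:
        lut = np.array(_ENCODINGS[m])
        x = lut[codes]
        _, p = _ols_scan(y, x)
        rows[m] = p

    n_var = (codes == 2).sum(axis=0)
    table = pd.DataFrame({"site_id": site_cols})
    for m in MODELS:
        table[f"p_{m}"] = rows.get(m, np.full(len(site_cols), np.nan))
    pmat = table[[f"p_{m}" for m in models]].to_numpy()
    all_nan = np.all(np.isnan(pmat), axis=1)
    with np.errstate(invalid="ignore"):
        best_idx = np.where(all_nan, 0, np.nanargmin(np.where(np.isnan(pmat), np.inf, pmat), axis=1))
    best_p = np.where(all_nan, np.nan, pmat[np.arange(len(pmat)), best_idx])
    table["best_model"] = np.where(all_nan, "none", np.array(models)[best_idx])
    table["best_p"] = best_p
    with np.errstate(invalid="ignore"):
        table["neglog10p"] = -np.log10(best_p)
    table["n_VAR"] = n_var
    table["n"] = len(y)
    table["status"] = np.where(all_nan, "degenerate", "ok")

    if sites is not None:
        ann = sites[["site_id", "chromosome", "position_bp", "gene"]]
        table = table.merge(ann, on="site_id", how="left")
        table = table[
            ["site_id", "chromosome", "position_bp", "gene", "best_model"]
            + [f"p_{m}" for m in MODELS]
            + ["best_p", "neglog10p", "n_VAR", "n", "status"]
        ]
    return table


def call_candidates(manhattan: pd.DataFrame, threshold: float) -> list[CandidateCall]:
    """Apply the two candidate criteria to the scan's lead peak.

    The lead site is the one with the largest -log10 best p.  Criterion 1:
    best p strictly below the Bonferroni threshold.  Criterion 2: the lead
    peak exceeds the highest peak at any *other gene* by >= 3 logs (margin
    +inf when the pedigree has a single tested gene).  Returns a single-entry
    list describing the lead peak, or an empty list when every site is
    degenerate.
    """
    if len(manhattan) == 0:
        raise ValueError("Manhattan table is empty")
    ok = manhattan[manhattan["status"] == "ok"]
    if len(ok) == 0:
        return []
    lead = ok.loc[ok["neglog10p"].idxmax()]
    genes = ok["gene"] if "gene" in ok.columns else ok["site_id"]
    lead_gene = lead["gene"] if "gene" in ok.columns else lead["site_id"]
    others = ok[genes != lead_gene]
    if len(others) == 0:
        margin = math.inf
    else:
        margin = float(lead["neglog10p"] - others["neglog10p"].max())
    above = bool(lead["best_p"] < threshold)
    return [
        CandidateCall(
            site_id=str(lead["site_id"]),
            above_threshold=above,
            margin_logs=margin,
            is_candidate=above and margin >= 3.0,
        )
    ]


@dataclass(frozen=True)
class PedigreeConfig:
    """Shape of the replicate pedigrees used by the power driver."""

    n_sites: int = 60
    n_g2_dams: int = 5
    n_g3_per_dam: int = 8
    effect_class_probs: tuple[float, float, float, float] = (0.10, 0.25, 0.25, 0.40)
    #: with a causal site, redraw the breeding until at least this many G3
    #: mice are VAR there (the screen's informative pedigrees have >= 2
    #: homozygotes); 0 disables the conditioning
    min_var_carriers: int = 2


def _child_rng(master_seed: int, rep: int) -> np.random.Generator:
    # documented fan-out rule: child entropy = (master_seed, replicate index)
    return np.random.default_rng(np.random.SeedSequence([master_seed, rep]))


def simulate_replicate(
    config: PedigreeConfig,
    phenotype_model: PhenotypeModel,
    causal: bool,
    rng: np.random.Generator,
    max_redraws: int = 1000,
):
    """One end-to-end replicate: breed, phenotype, score.

    Returns (pedigree, causal_site_id or None, phenotype table).  With a
    causal site the breeding is redrawn until the site carries at least
    ``config.min_var_carriers`` VAR G3 mice.
    """
    sites = draw_mutation_set(config.n_sites, config.effect_class_probs, rng)
    causal_site = sites[len(sites) // 2].site_id if causal else None
    for _ in range(max_redraws):
        ped = breed_pedigree(sites, config.n_g2_dams, config.n_g3_per_dam, rng)
        if causal_site is None or config.min_var_carriers == 0:
            break
        n_var = int(np.sum(ped.genotypes_at(causal_site, "G3") == 2))
        if n_var >= config.min_var_carriers:
            break
    else:
        raise RuntimeError("could not draw a pedigree with enough VAR carriers")
    exams = simulate_exams(ped, causal_site, phenotype_model, rng)
    pheno = phenotype_table(exams)
    return ped, causal_site, pheno


def _dichotomized_scan(
    affected: np.ndarray, codes: np.ndarray, site_cols: list[str], models: list[str]
) -> pd.DataFrame:
    rows = []
    for j, sid in enumerate(site_cols):
        per_model = {}
        for m in models:
            res = ordinal_association_test(affected, codes[:, j], m)
            per_model[m] = res.p if res.status == "ok" else np.nan
        ps = np.array([per_model[m] for m in models])
        if np.all(np.isnan(ps)):
            best_model, best_p = "none", np.nan
        else:
            k = int(np.nanargmin(np.where(np.isnan(ps), np.inf, ps)))
            best_model, best_p = models[k], float(ps[k])
        rows.append(
            {
                "site_id": sid,
                **{f"p_{m}": per_model.get(m, np.nan) for m in MODELS},
                "best_model": best_model,
                "best_p": best_p,
                "neglog10p": -math.log10(best_p) if best_p == best_p else np.nan,
                "n_VAR": int(np.sum(codes[:, j] == 2)),
                "n": len(affected),
                "status": "ok" if best_p == best_p else "degenerate",
            }
        )
    return pd.DataFrame.from_records(rows)


def power_study(
    pedigree_config: PedigreeConfig,
    phenotype_model: PhenotypeModel,
    causal: bool,
    n_reps: int,
    encoding_mode: str = "continuous",
    seed: int = 0,
    models: Iterable[str] = MODELS,
    alpha: float = 0.05,
    dichotomize_cut: int = 6,
    collect_pvalues: bool = False,
) -> PowerReport:
    """Replicate-pedigree simulation of detection power or false-candidate rate.

    Each replicate breeds a pedigree, simulates fundus exams, scores them,
    scans all sites under the requested models and applies the candidate
    criteria.  With ``causal=True``, power is the fraction of replicates in
    which the causal site itself is called candidate; with ``causal=False``
    the family-wise false-candidate rate is the fraction of replicates with
    any candidate at all.  ``per_model_power`` attributes each detection to
    the model that achieved the winning p-value.

    ``encoding_mode='continuous'`` regresses on the 0-8 mouse score;
    ``'dichotomized'`` tests affected (score >= ``dichotomize_cut``) status
    with the exact 2x2 test.  Replicate r uses the child generator seeded
    from (seed, r), so any replicate is individually reproducible.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if encoding_mode not in ("continuous", "dichotomized"):
        raise ValueError(f"unknown encoding_mode {encoding_mode!r}")
    models = list(models)

    n_detected = 0
    n_any_candidate = 0
    per_model_hits = {m: 0 for m in models}
    collected: dict[str, list[np.ndarray]] = {m: [] for m in models}
    threshold = bonferroni_threshold(pedigree_config.n_sites, len(models), alpha)

    for rep in range(n_reps):
        rng = _child_rng(seed, rep)
        ped, causal_site, pheno = simulate_replicate(
            pedigree_config, phenotype_model, causal, rng
        )
        geno = genotype_table(ped, "G3")
        ann = mutation_table(ped)
        if encoding_mode == "continuous":
            manhattan = scan_pedigree(pheno, geno, models, sites=ann)
        else:
            ordered = geno.set_index("mouse_id").loc[pheno["mouse_id"]].reset_index()
            site_cols, codes = _genotype_codes_from_table(ordered)
            affected = (pheno["mouse_score"] >= dichotomize_cut).to_numpy()
            manhattan = _dichotomized_scan(affected, codes, site_cols, models)
            manhattan = manhattan.merge(
                ann[["site_id", "chromosome", "position_bp", "gene"]], on="site_id", how="left"
            )
        calls = call_candidates(manhattan, threshold)
        if calls and calls[0].is_candidate:
            n_any_candidate += 1
            if causal and calls[0].site_id == causal_site:
                n_detected += 1
                row = manhattan.loc[manhattan["site_id"] == causal_site].iloc[0]
                if row["best_model"] in per_model_hits:
                    per_model_hits[row["best_model"]] += 1
        if collect_pvalues:
            for m in models:
                ps = manhattan[f"p_{m}"].to_numpy(dtype=float)
                collected[m].append(ps[~np.isnan(ps)])

    return PowerReport(
        n_reps=n_reps,
        power=n_detected / n_reps,
        familywise_fp_rate=n_any_candidate / n_reps,
        per_model_power={m: per_model_hits[m] / n_reps for m in models},
        encoding_mode=encoding_mode,
        seed=seed,
        pvalues={m: np.concatenate(v) if v else np.array([]) for m, v in collected.items()}
        if collect_pvalues
        else {},
    )
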