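"""End-to-end screen pipeline: simulate, score, map, call, report."""

from __future__ import annotations

import datetime
import sys
from pathlib import Path

import numpy as np
import pandas as pd

import fundusmap
from fundusmap.config import RunConfig
from fundusmap.io import write_table
from fundusmap.linkage import (
    bonferroni_threshold,
    call_candidates,
    scan_pedigree,
    simulate_replicate,
)
from fundusmap.pedigree import genotype_table, mutation_table
from fundusmap.plot import manhattan_plot


def run_screen(config: RunConfig, make_plot: bool = True) -> Path:
    """Run one simulated pedigree through the whole screen.

    Writes genotypes.tsv, mutations.tsv, phenotypes.tsv, manhattan.tsv,
    candidates.tsv, the serialized config and a run log (seed, config hash,
    versions) into ``config.out_dir``; optionally a Manhattan plot.  The
    whole run is deterministic given the master seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))

    ped, causal_site, pheno = simulate_replicate(
        config.pedigree_config(), config.phenotype_model(), config.causal, rng
    )
    geno = genotype_table(ped, "G3")
    ann = mutation_table(ped)
    manhattan = scan_pedigree(pheno, geno, config.models, sites=ann)
    n_models = len(config.models) if config.bonferroni_count_models else 1
    threshold = bonferroni_threshold(config.n_sites, n_models, config.alpha)
    calls = call_candidates(manhattan, threshold)

    write_table(genotype_table(ped), out / "genotypes.tsv")
    write_table(ann, out / "mutations.tsv")
    write_table(pheno, out / "phenotypes.tsv")
    write_table(manhattan, out / "manhattan.tsv")
    cand_df = pd.DataFrame.from_records(
        [
            {
                "site_id": c.site_id,
                "above_threshold": c.above_threshold,
                "margin_logs": c.margin_logs,
                "is_candidate": c.is_candidate,
            }
            for c in calls
            if c.is_candidate
        ],
        columns=["site_id", "above_threshold", "margin_logs", "is_candidate"],
    )
    write_table(cand_df, out / "candidates.tsv")
    config.to_file(out / "config.yaml")
    if make_plot:
        manhattan_plot(manhattan, threshold, out / "manhattan.png")

    log_lines = [
        f"timestamp\t{datetime.datetime.now(datetime.timezone.utc).isoformat()}",
        f"fundusmap_version\t{fundusmap.__version__}",
        f"python_version\t{sys.version.split()[0]}",
        f"numpy_version\t{np.__version__}",
        f"master_seed\t{config.seed}",
        f"config_hash\t{config.config_hash()}",
        f"causal_site\t{causal_site if causal_site else 'none'}",
        f"bonferroni_threshold\t{threshold:.6e}",
        f"n_candidates\t{len(cand_df)}",
    ]
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return out
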