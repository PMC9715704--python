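"""End-to-end pipeline: QC -> filters -> assignment -> refinement -> dating
-> diversity, driven by a single config mapping and one master seed.

Every stage draws its randomness from a sub-seed spawned deterministically
from the master seed, and every filter decision is written to the run log,
so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import haplogroups as hg
from . import io as yio
from . import phylo, popstats, qc, rho
from .core import GenotypeMatrix, MutationRateSpec

DEFAULT_PARAMS = {
    "min_median_depth": 4.0,
    "min_fold_increase": 5.0,
    "max_missing": 0.05,
    "window": 10_000,
    "mu": 0.76e-9,
    "mu_low": 0.67e-9,
    "mu_high": 0.86e-9,
    "length": 8_900_000,
    "genome_size": 6_000_000_000,
    "bias_merge_distance": 5_000,
    "bias_q": 0.01,
    "n_permutations": 10_000,
    "n_sims": 100_000,
    "seed": 1,
}


class PipelineError(RuntimeError):
    pass


def _load_config(config) -> dict:
    if isinstance(config, (str, os.PathLike)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    return config


def run_pipeline(config, outdir: str | os.PathLike | None = None) -> dict:
    """Run every stage the config provides inputs for; returns a summary
    dict and writes the report bundle under ``outdir``.

    ``config`` is a mapping (or YAML path) with keys ``inputs`` (paths:
    vcf, meta, regions_bed, tree_yaml, counts_tsv, depths_tsv), ``params``
    and ``outdir``.  Missing input files abort before any stage runs.
    """
    config = _load_config(config)
    inputs = config.get("inputs", {})
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    outdir = Path(outdir or config.get("outdir", "ydna_out"))

    for key, path in inputs.items():
        if path is not None and not os.path.exists(path):
            raise PipelineError(f"input {key!r} not found: {path}")
    required = ["vcf", "meta", "regions_bed"]
    for key in required:
        if not inputs.get(key):
            raise PipelineError(f"config must name input {key!r}")

    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    seeds = np.random.SeedSequence(int(params["seed"])).spawn(4)
    sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]
    log.append(f"master seed {params['seed']}; stage sub-seeds {sub_seeds}")

    regions = yio.read_bed(inputs["regions_bed"])
    meta = yio.read_sample_table(inputs["meta"])
    rate = MutationRateSpec(
        mu_point=params["mu"], mu_low=params["mu_low"], mu_high=params["mu_high"],
        length=int(params["length"]),
    )
    summary: dict = {"params": params}

    # --- stage 1: capture QC and sample filters ---------------------------
    kept_samples: list[str] | None = None
    if inputs.get("counts_tsv") and inputs.get("depths_tsv"):
        counts = yio.read_counts_table(inputs["counts_tsv"])
        depths = yio.read_depth_table(inputs["depths_tsv"])
        metrics = qc.compute_capture_metrics(
            counts, depths, regions,
            window=int(params["window"]), genome_size=int(params["genome_size"]),
        )
        kept_samples, discard = qc.filter_samples(
            metrics,
            min_median_depth=params["min_median_depth"],
            min_fold_increase=params["min_fold_increase"],
        )
        metrics.per_sample.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        discard.to_csv(outdir / "sample_filter.tsv", sep="\t", index=False)
        for _, row in discard.iterrows():
            log.append(f"discard sample {row['sample_id']}: {row['reason']}")
        summary["qc"] = {
            "n_samples": int(len(counts)),
            "n_kept": len(kept_samples),
            "n_discarded": int(len(discard)),
        }

    # --- stage 2: genotypes and SNP-level filters -------------------------
    matrix = yio.read_haploid_vcf(inputs["vcf"])
    if kept_samples is not None:
        keep = [s for s in matrix.sample_ids if s in set(kept_samples)]
        dropped = [s for s in matrix.sample_ids if s not in set(kept_samples)]
        if dropped:
            # genotyped samples absent from the QC tables (e.g. WGS) pass
            genotyped_only = [s for s in dropped if s not in set(counts["sample_id"])]
            keep = keep + genotyped_only
            keep = [s for s in matrix.sample_ids if s in set(keep)]
            for s in set(dropped) - set(genotyped_only):
                log.append(f"sample {s} removed from matrix by QC filter")
        matrix = matrix.select_samples(keep)
    n_input_snps = matrix.n_snps

    platforms = pd.Series(meta["platform"].values, index=meta["sample_id"])
    bias = phylo.reference_bias_screen(
        matrix, platforms,
        merge_distance=int(params["bias_merge_distance"]),
        q_threshold=params["bias_q"],
    )
    matrix = phylo.apply_bias_filter(matrix, bias)
    log.append(
        f"reference-bias screen: {bias.n_snps_removed} SNPs in "
        f"{len(bias.fragments)} fragments ({bias.bp_removed} bp) removed"
    )

    matrix, removed = phylo.snp_missingness_filter(matrix, params["max_missing"])
    log.append(f"missingness filter (<{params['max_missing']}): {len(removed)} SNPs removed")
    summary["snp_filters"] = {
        "n_input_snps": n_input_snps,
        "n_bias_removed": bias.n_snps_removed,
        "n_missingness_removed": len(removed),
        "n_retained": matrix.n_snps,
    }

    # --- stage 3: haplogroup assignment -----------------------------------
    calls = None
    if inputs.get("tree_yaml"):
        tree = yio.read_tree_spec(inputs["tree_yaml"])
        calls = hg.assign_all(matrix, tree, region_set=regions)
        ct = hg.calls_table(calls)
        ct.to_csv(outdir / "haplogroup_calls.tsv", sep="\t", index=False)
        meta_matrix = meta[meta["sample_id"].isin(matrix.sample_ids)]
        freqs = hg.haplogroup_frequencies(calls, meta_matrix, denominator="all")
        freqs.to_csv(outdir / "haplogroup_frequencies.tsv", sep="\t", index=False)
        summary["assignment"] = {
            "n_called": len(calls),
            "n_flagged": int(ct["flagged"].sum()),
            "n_starred": int(ct["starred"].sum()),
        }

        # --- stage 4: phylogeny refinement --------------------------------
        pp = phylo.build_perfect_phylogeny(matrix)
        refinement = {
            "n_root_branches": pp.n_root_branches,
            "n_singleton_branches": pp.n_singleton_branches,
            "n_quarantined": int(len(pp.quarantined)),
            "bias_fragments": bias.fragments.to_dict(orient="records"),
            "bundles": {},
        }
        for name, node in tree.nodes.items():
            if node.bundle:
                in_matrix = [s for s in node.snps if s in matrix.snp_names]
                if in_matrix:
                    rep = phylo.resolve_bundle(in_matrix, matrix, tree)
                    refinement["bundles"][name] = rep.to_dict(orient="records")
        with open(outdir / "refinement.json", "w") as fh:
            json.dump(refinement, fh, indent=2, sort_keys=True)
        with open(outdir / "phylogeny.nwk", "w") as fh:
            fh.write(pp.to_newick() + "\n")
        summary["refinement"] = {
            k: refinement[k]
            for k in ("n_root_branches", "n_singleton_branches", "n_quarantined")
        }

    # --- stage 5: rho TMRCA -----------------------------------------------
    meta_matrix = meta[meta["sample_id"].isin(matrix.sample_ids)]
    pooled = rho.rho_tmrca(matrix, rate, group="Pooled")
    by_region = rho.tmrca_by_group(matrix, meta_matrix, rate, grouping="region")
    rho_table = pd.concat(
        [by_region, pd.DataFrame([pooled.__dict__])], ignore_index=True
    )
    rho_table.to_csv(outdir / "rho_report.tsv", sep="\t", index=False)
    summary["rho"] = {"pooled_tmrca": pooled.tmrca, "pooled_rho": pooled.rho}

    # --- stage 6: diversity, AMOVA, phi_ST, MDS ---------------------------
    div_rows = []
    region_of = dict(zip(meta_matrix["sample_id"], meta_matrix["region"]))
    labels = np.array([region_of[s] for s in matrix.sample_ids])
    rng_seed = sub_seeds[2]
    for g in sorted(pd.unique(labels)):
        sub = matrix.subset_samples(labels == g)
        if sub.n_samples < 4:
            log.append(f"diversity: region {g} skipped (n={sub.n_samples} < 4)")
            continue
        d = popstats.diversity(sub, int(params["length"]), group=g)
        if d.s >= 1 and int(params["n_sims"]) > 0:
            d.p_d = popstats.tajimas_d_pvalue(
                sub, n_sims=int(params["n_sims"]), seed=rng_seed
            )
        div_rows.append(d.__dict__)
    pooled_div = popstats.diversity(matrix, int(params["length"]), group="Pooled")
    if pooled_div.s >= 1 and int(params["n_sims"]) > 0:
        pooled_div.p_d = popstats.tajimas_d_pvalue(
            matrix, n_sims=int(params["n_sims"]), seed=rng_seed
        )
    div_rows.append(pooled_div.__dict__)
    pd.DataFrame(div_rows).to_csv(outdir / "diversity.tsv", sep="\t", index=False)

    big_enough = pd.Series(labels).value_counts()
    usable = big_enough[big_enough >= 2]
    amova_out = None
    if len(usable) >= 2:
        amova_out = popstats.amova(
            matrix, list(labels),
            n_permutations=int(params["n_permutations"]), seed=sub_seeds[3],
        )
        with open(outdir / "amova.json", "w") as fh:
            json.dump(amova_out.__dict__, fh, indent=2, sort_keys=True)
        phist = popstats.pairwise_phist(matrix, list(labels))
        phist.to_csv(outdir / "phist.tsv", sep="\t")
        if len(phist) >= 4:
            emb = popstats.mds(phist, k=2)
            emb.coords.assign(stress_pct=emb.stress_pct).to_csv(
                outdir / "mds.tsv", sep="\t"
            )
            summary["mds_stress_pct"] = emb.stress_pct
        summary["amova"] = {
            "phi_st": amova_out.phi_st,
            "pct_among": amova_out.pct_among,
            "p_value": amova_out.p_value,
        }
    summary["diversity"] = {"pooled_mpd": pooled_div.mpd, "pooled_s": pooled_div.s}

    with open(outdir / "pipeline_log.txt", "w") as fh:
        fh.write("\n".join(log) + "\n")
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary
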