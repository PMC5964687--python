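"""End-to-end orchestration: dataset -> per-rank report directory.

For each configured taxonomic rank the pipeline writes seven report kinds:
the normalized common-level table, a PCA report, a random-forest report, the
pairwise-ensemble metrics, the Tukey replicate summary, the diversity
permutation-test results, and the per-city co-abundance networks, plus a run
manifest echoing the seed and configuration.  Any stage failure aborts the
run with the stage name; the manifest then marks the run incomplete.
"""

from __future__ import annotations

import json
import logging
from itertools import combinations
from pathlib import Path

import pandas as pd

from . import abundance, classification, diversity, network, ordination, preprocess
from .config import PipelineConfig
from .datatypes import OtuDataset
from .errors import CityprintsError, PreconditionError
from .io import write_result_table
from .rng import stage_seed

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _prepare_rank(dataset, rank, config):
    table = preprocess.aggregate_to_rank(dataset, rank)
    totals = table.counts.sum(axis=0)
    keep = totals >= config.min_sample_total
    if not keep.all():
        dropped = list(table.counts.columns[~keep])
        logger.warning("rank %s: dropping %d low-count samples: %s",
                       rank, len(dropped), dropped[:5])
        table.counts = table.counts.loc[:, keep.to_numpy()]
        table.meta = table.meta.loc[keep.to_numpy()]
    per_city = preprocess.split_by_city(table)
    common, venn = preprocess.common_levels(per_city)
    if config.normalize_per_city:
        pieces = [
            preprocess.normalize_log_cpm(
                preprocess.restrict_to_common(t, common)
            )
            for t in per_city.values()
        ]
        values = pd.concat([p.values for p in pieces], axis=1)
        values = values[list(table.meta.index)]
        norm = preprocess.NormalizedTable(
            rank=rank, values=values, meta=table.meta, common_only=True
        )
    else:
        norm = preprocess.normalize_log_cpm(
            preprocess.restrict_to_common(table, common)
        )
    return table, norm, common, venn


def run_pipeline(config: PipelineConfig, dataset: OtuDataset, outdir) -> Path:
    """Run every stage for every configured rank and write all reports."""
    config.validate()
    dataset.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    chash = config.config_hash()

    city_sizes = dataset.metadata_frame()["city"].value_counts()
    if config.subsample_size > city_sizes.min():
        raise PreconditionError(
            f"subsample_size={config.subsample_size} exceeds smallest city "
            f"({city_sizes.idxmin()}: {int(city_sizes.min())} samples)"
        )

    manifest = {
        "seed": seed,
        "config_hash": chash,
        "config": config.to_dict(),
        "status": "incomplete",
        "stages": {},
    }

    def _write_manifest():
        with (outdir / "manifest.json").open("w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    stage = "setup"
    try:
        for rank in config.ranks:
            rankdir = outdir / rank
            rankdir.mkdir(exist_ok=True)

            stage = f"{rank}/preprocess"
            table, norm, common, venn = _prepare_rank(dataset, rank, config)
            write_result_table(norm.values, rankdir / "normalized.tsv",
                               seed=seed, config_hash=chash)
            ks = preprocess.ks_platform_check(norm)
            if not ks.skipped:
                write_result_table(ks.table, rankdir / "ks_platform.tsv",
                                   seed=seed, config_hash=chash)
            manifest["stages"][stage] = {
                "n_common_levels": len(common),
                "ks_skipped": ks.skipped,
                "ks_p_min": ks.p_min,
                "ks_p_max": ks.p_max,
            }

            stage = f"{rank}/pca"
            pca = ordination.run_pca(norm)
            k3 = min(3, pca.n_components)
            variance = pd.DataFrame(
                {
                    "eigenvalue": pca.eigenvalues,
                    "proportion": pca.proportions,
                    "cumulative": pca.proportions.cumsum(),
                },
                index=[f"PC{i + 1}" for i in range(pca.n_components)],
            )
            write_result_table(variance, rankdir / "pca_variance.tsv",
                               seed=seed, config_hash=chash)
            write_result_table(pca.scores, rankdir / "pca_scores.tsv",
                               seed=seed, config_hash=chash)
            write_result_table(pca.loadings, rankdir / "pca_loadings.tsv",
                               seed=seed, config_hash=chash)
            manifest["stages"][stage] = {
                "variance_first_3": ordination.variance_explained(pca, k3)
            }

            stage = f"{rank}/random_forest"
            rf = classification.rf_city_classifier(
                norm, trees=config.rf_trees,
                vars_per_split=config.rf_vars_per_split,
                seed=stage_seed(seed, stage),
            )
            write_result_table(rf.per_city_error.to_frame(),
                               rankdir / "rf_errors.tsv",
                               seed=seed, config_hash=chash,
                               extra=f"overall_oob={rf.oob_error:.6f}")
            write_result_table(rf.importance, rankdir / "rf_importance.tsv",
                               seed=seed, config_hash=chash)
            manifest["stages"][stage] = {"oob_error": rf.oob_error}

            stage = f"{rank}/ensemble"
            components = {
                name: est
                for name, est in classification.default_components(
                    stage_seed(seed, stage)
                ).items()
                if name in config.ensemble_components
            }
            ens_rows = []
            for pair in combinations(sorted(norm.cities()), 2):
                report = classification.ensemble_pairwise(
                    norm, pair, folds=config.ensemble_folds,
                    iterations=config.ensemble_iterations,
                    seed=stage_seed(seed, f"{stage}/{pair}"),
                    components=components,
                )
                frame = report.metrics.copy()
                frame.insert(0, "pair", f"{pair[0]}-{pair[1]}")
                ens_rows.append(frame)
            ens = pd.concat(ens_rows)
            write_result_table(ens, rankdir / "ensemble_metrics.tsv",
                               seed=seed, config_hash=chash)
            manifest["stages"][stage] = {
                "mean_accuracy": float(ens["accuracy"].mean())
            }

            stage = f"{rank}/anova"
            tukey = abundance.replicate_summary(
                norm, replicates=config.anova_replicates,
                n=config.subsample_size, fdr=config.fdr,
                tukey_alpha=config.tukey_alpha,
                seed=stage_seed(seed, stage),
            )
            write_result_table(
                tukey.to_frame(), rankdir / "tukey_summary.tsv",
                seed=seed, config_hash=chash, index=False,
                extra=(f"replicates={tukey.replicates} "
                       f"n={tukey.subsample_size} "
                       f"city_order={','.join(tukey.city_order)}"),
            )
            manifest["stages"][stage] = {"replicates": tukey.replicates}

            stage = f"{rank}/diversity"
            div_rows = []
            for q in config.q_values:
                result = diversity.permutation_test(
                    table, q=q, n_permutations=config.permutations,
                    seed=stage_seed(seed, f"{stage}/q{q}"),
                )
                row = {"q": q, "p_value": result.p_value,
                       "theta": result.theta, **{
                           f"alpha_{c}": a for c, a in result.alphas.items()
                       }}
                div_rows.append(row)
            div = pd.DataFrame(div_rows).set_index("q")
            write_result_table(div, rankdir / "diversity_test.tsv",
                               seed=seed, config_hash=chash,
                               extra=f"bootstrap_replications={config.permutations}")
            manifest["stages"][stage] = {
                "p_values": {str(r["q"]): r["p_value"] for r in div_rows}
            }

            stage = f"{rank}/network"
            nets = {}
            edge_frames = []
            for city in norm.cities():
                corr = network.correlation_matrix(norm, city)
                target = min(config.network_target_nodes, corr.shape[0])
                threshold = network.calibrate_threshold(
                    corr, target, config.network_tolerance
                )
                net = network.threshold_network(corr, threshold,
                                                city=city, rank=rank)
                nets[city] = net
                edge_frames.append(net.edge_frame())
                try:
                    import networkx as nx
                    nx.write_graphml(net.graph,
                                     rankdir / f"network_{city}.graphml")
                except Exception:      # GraphML export is best-effort
                    logger.warning("GraphML export failed for %s", city)
            edges = pd.concat(edge_frames, ignore_index=True)
            write_result_table(edges, rankdir / "network_edges.tsv",
                               seed=seed, config_hash=chash, index=False)
            summary = network.network_summary(nets)
            manifest["stages"][stage] = {
                "nodes": {c: s["n_nodes"] for c, s in
                          summary["per_city"].items()},
                "shared_hubs": summary["shared_hubs"],
            }
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_manifest()
        if isinstance(exc, CityprintsError):
            raise
        raise CityprintsError(f"stage {stage!r} failed: {exc}") from exc

    manifest["status"] = "complete"
    _write_manifest()
    return outdir
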