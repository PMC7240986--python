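"""End-to-end orchestration: normalize -> filter -> fit -> summarize.

Composes the stages in analysis order on real or synthetic inputs and
writes a reproducible result bundle (fits table, group summary, optional
predictor correlations and module/covariance-ratio results, plus a manifest
recording the configuration hash and seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from coevo import __version__
from coevo import benchmark, diagnostics, modularity, normalize, pairstats, phylo
from coevo.synthetic import PairRecord

__all__ = ["RunConfig", "validate_inputs", "run_full_analysis", "read_pairs_tsv"]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Paths and flags of one full analysis run."""

    tree: str
    mean: str
    se: str = None
    pairs: str = None
    network: str = None
    out_dir: str = "coevo_out"
    bm_filter: bool = True
    bm_diagnostic: str = "abs"
    statistic: str = "rho_c"
    bin_width: float = 0.05
    min_confidence: float = None
    seed: int = 0
    n_permutations: int = 999
    mcl_inflation: float = 2.0
    module_min_size: int = 15

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_pairs_tsv(path) -> list:
    """Read a gene-pair table (gene1, gene2 [, group, confidence, ...])."""
    df = pd.read_csv(path, sep="\t")
    recs = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        recs.append(PairRecord(
            gene1=str(d["gene1"]), gene2=str(d["gene2"]),
            group=str(d.get("group", "binding")),
            confidence=d.get("confidence"),
            degree1=d.get("degree1"), degree2=d.get("degree2"),
        ))
    return recs


def load_panel(mean_path, se_path=None) -> normalize.ExpressionPanel:
    mean = pd.read_csv(mean_path, sep="\t", index_col=0)
    if se_path:
        se = pd.read_csv(se_path, sep="\t", index_col=0)
    else:
        se = pd.DataFrame(0.0, index=mean.index, columns=mean.columns)
    return normalize.ExpressionPanel(mean, se)


def validate_inputs(config: RunConfig) -> dict:
    """Check path existence and species-name agreement; report orphans."""
    report = {"errors": [], "warnings": []}
    for name in ("tree", "mean", "se", "pairs", "network"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            report["errors"].append("%s path does not exist: %s" % (name, p))
    if report["errors"]:
        return report
    tree = phylo.read_newick(config.tree)
    panel = load_panel(config.mean, config.se)
    tree_sp, panel_sp = set(tree.tip_labels), set(panel.species)
    shared = tree_sp & panel_sp
    report["n_shared_species"] = len(shared)
    report["tree_only"] = sorted(tree_sp - panel_sp)
    report["panel_only"] = sorted(panel_sp - tree_sp)
    if len(shared) < 3:
        report["errors"].append(
            "fewer than 3 species shared between tree and expression panel"
        )
    elif report["tree_only"]:
        report["warnings"].append(
            "tree will be pruned to the %d shared species" % len(shared)
        )
    return report


def run_full_analysis(config: RunConfig) -> dict:
    """Run the full analysis and write the result bundle.

    Stages: input validation, completeness filtering, Brownian-Motion
    assumption screen, per-pair model fits with LRT and BH correction,
    group-level summary, optional weighted-Spearman predictor correlations,
    and optional network modules with the covariance-ratio test.
    """
    report = validate_inputs(config)
    if report["errors"]:
        raise ValueError("input validation failed: %s" % "; ".join(report["errors"]))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = phylo.read_newick(config.tree)
    panel = load_panel(config.mean, config.se)
    shared = [s for s in tree.tip_labels if s in set(panel.species)]
    if len(shared) < tree.n_tips:
        tree = phylo.prune(tree, shared)
    pairs = read_pairs_tsv(config.pairs) if config.pairs else []
    if config.min_confidence is not None:
        pairs = [p for p in pairs
                 if p.confidence is None or p.confidence >= config.min_confidence]

    panel, pairs, dropped = normalize.filter_complete(panel, pairs)
    pairs, bm_report = diagnostics.filter_bm(
        panel, tree, pairs, enabled=config.bm_filter,
        diagnostic=config.bm_diagnostic,
    )
    cov = phylo.vcv(tree)
    fits = benchmark.fit_pair_table(cov, panel, pairs)
    if len(fits):
        fits["q_lrt"] = pairstats.bh_adjust(fits["p_lrt"].to_numpy())
    fits.to_csv(out / "fits.tsv", sep="\t", index=False)

    results = {"fits": fits}
    summary = {}
    b = fits[fits["group"] == "binding"] if len(fits) else fits
    c = fits[fits["group"] == "control"] if len(fits) else fits
    if len(b) >= 2 and len(c) >= 2:
        for stat in ("rho_c", "rho_u"):
            summary[stat] = pairstats.group_tests(b[stat], c[stat])
    with open(out / "group_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    results["group_summary"] = summary

    predictors = {}
    if len(b) >= 4:
        cols = {"confidence": "string_score"}
        pb = [p for p in pairs if p.group == "binding"]
        conf = np.array([p.confidence for p in pb], dtype=float)
        if np.isfinite(conf).all():
            ws = pairstats.weighted_spearman(
                conf, b["rho_c"].to_numpy(), pairs=pb, seed=config.seed,
            )
            predictors["string_score"] = dataclasses.asdict(ws)
    pd.DataFrame(predictors).to_csv(out / "predictors.tsv", sep="\t")
    results["predictors"] = predictors

    if config.network:
        graph = modularity.read_edge_list(config.network)
        labels = modularity.mcl(graph, inflation=config.mcl_inflation)
        pd.Series(labels, name="module").rename_axis("gene").to_csv(
            out / "modules.tsv", sep="\t"
        )
        module_genes = [g for g in labels if g in set(panel.genes)]
        if module_genes:
            X = panel.mean.loc[cov.species, module_genes].to_numpy()
            Xt = modularity.phylo_transform(X, cov)
            try:
                cr = modularity.covariance_ratio(
                    Xt, [labels[g] for g in module_genes],
                    n_perm=config.n_permutations, seed=config.seed,
                    min_size=config.module_min_size,
                )
                cr_out = {"cr": cr.cr, "p_value": cr.p_value,
                          "n_permutations": cr.n_permutations}
            except ValueError as exc:
                cr_out = {"error": str(exc)}
            with open(out / "cr.json", "w") as fh:
                json.dump(cr_out, fh, indent=2)
            results["cr"] = cr_out

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "n_pairs_fit": int(len(fits)),
        "n_genes_dropped_missing": len(dropped),
        "n_genes_bm_violating": sum(1 for v in bm_report.values() if v[2]),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["manifest"] = manifest
    return results
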