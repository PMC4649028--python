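"""End-to-end orchestration: subsample -> filter -> network -> clusters -> reports.

Stages communicate through fixed-name TSV artifacts in a run directory, so
each stage can also be run on its own (see :mod:`soilnet.cli`) and a
composed run is identical to :func:`run_pipeline`.  Every stage is seeded
from the config; a repeated run with the same config writes byte-identical
numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compartment_analysis as ca
from . import coocc_network as net
from . import diversity_stats as ds
from . import markov_stability as ms
from . import preprocess as pp
from . import synthetic_data as sd
from . import tables_io as tio

_FLOAT_FMT = "%.10g"


@dataclass
class InputConfig:
    counts: str | None = None
    counts_dialect: str = "tsv"
    metadata: str | None = None
    taxonomy: str | None = None
    taxonomy_dialect: str = "tsv"
    copy_numbers: str | None = None
    qpcr: str | None = None


@dataclass
class NetworkConfig:
    n_iter: int = 1000
    seed: int | None = None
    rho_pos: float = 0.6
    rho_neg: float = -0.6
    alpha: float = 0.05


@dataclass
class StabilityConfig:
    mode: str = "auto"  # auto | linearized | exponential
    n_restarts: int = 20
    seed: int | None = None
    t_min: float = 1e-2
    t_max: float = 1e2
    n_times: int = 60
    k_min: int = 3
    vi_tol: float | None = None


@dataclass
class RunConfig:
    output_dir: str = "run"
    input: InputConfig = field(default_factory=InputConfig)
    preprocess: pp.PreprocessConfig = field(default_factory=pp.PreprocessConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    core_sd_rule: bool = True
    ternary_min_abundance: int = 5
    permanova_seed: int | None = None
    permanova_n_perm: int = 999
    simulate: dict | None = None  # SyntheticDesign kwargs, or None

    def validate(self) -> None:
        """Fail before any compute when a required seed is missing."""
        missing = []
        if self.network.seed is None:
            missing.append("network.seed")
        if self.stability.seed is None:
            missing.append("stability.seed")
        if self.permanova_seed is None:
            missing.append("permanova_seed")
        if self.preprocess.seed is None:
            missing.append("preprocess.seed")
        if missing:
            raise ValueError(f"config must set explicit seeds: {missing}")
        net.Thresholds(self.network.rho_pos, self.network.rho_neg,
                       self.network.alpha)
        if self.simulate is None and (
            self.input.counts is None or self.input.metadata is None
        ):
            raise ValueError(
                "config needs input.counts and input.metadata, or a "
                "'simulate' section"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cfg = cls()
        for key, value in raw.items():
            if key == "input":
                cfg.input = InputConfig(**value)
            elif key == "preprocess":
                cfg.preprocess = pp.PreprocessConfig(**value)
            elif key == "network":
                cfg.network = NetworkConfig(**value)
            elif key == "stability":
                cfg.stability = StabilityConfig(**value)
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _run(stage: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage {stage!r} failed: {exc}") from exc

        return wrapped

    return deco


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


@_run("simulate")
def stage_simulate(config: RunConfig, outdir: Path) -> sd.SyntheticBundle:
    design = sd.SyntheticDesign(**(config.simulate or {}))
    bundle = sd.generate_dataset(design)
    tio.write_count_table(bundle.table, outdir / "counts.tsv")
    meta = bundle.metadata.table.copy()
    meta.index.name = "sample_id"
    _write(meta, outdir / "metadata.tsv")
    lineage = bundle.taxonomy.lineage.copy()
    lineage.index.name = "otu_id"
    _write(lineage, outdir / "taxonomy.tsv")
    cn_rows = [
        {"rank": r, "name": n, "mean_copies": v}
        for (r, n), v in bundle.copy_numbers.entries.items()
    ]
    _write(pd.DataFrame(cn_rows), outdir / "copy_numbers.tsv", index=False)
    _write(bundle.qpcr_totals.to_frame(), outdir / "qpcr.tsv")
    truth = pd.DataFrame(
        {"role": pd.Series(bundle.truth.otu_roles)}
    )
    truth.index.name = "otu_id"
    _write(truth, outdir / "truth.tsv")
    return bundle


def _load_inputs(config: RunConfig, outdir: Path):
    inp = config.input
    counts_path = inp.counts or outdir / "counts.tsv"
    meta_path = inp.metadata or outdir / "metadata.tsv"
    table = tio.read_count_table(counts_path, inp.counts_dialect)
    meta = tio.read_metadata(meta_path)
    tax = None
    tax_path = inp.taxonomy or (
        outdir / "taxonomy.tsv" if (outdir / "taxonomy.tsv").exists() else None
    )
    if tax_path:
        tax = _read_taxonomy_table(tax_path, inp.taxonomy_dialect)
    cn = None
    cn_path = inp.copy_numbers or (
        outdir / "copy_numbers.tsv"
        if (outdir / "copy_numbers.tsv").exists()
        else None
    )
    if cn_path:
        cn = tio.read_copy_numbers(cn_path)
    qpcr = None
    qpcr_path = inp.qpcr or (
        outdir / "qpcr.tsv" if (outdir / "qpcr.tsv").exists() else None
    )
    if qpcr_path:
        qpcr = pd.read_csv(qpcr_path, sep="\t", index_col=0).iloc[:, 0]
    return table, meta, tax, cn, qpcr


def _read_taxonomy_table(path, dialect: str) -> tio.TaxonomyTable:
    # rank-per-column TSVs (our own export) vs lineage-string dialects
    head = pd.read_csv(path, sep="\t", nrows=0)
    if set(tio.RANKS) <= set(head.columns):
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        return tio.TaxonomyTable(df[list(tio.RANKS)])
    return tio.read_taxonomy(path, dialect)


@_run("preprocess")
def stage_preprocess(config: RunConfig, outdir: Path) -> dict:
    table, meta, tax, cn, qpcr = _load_inputs(config, outdir)
    tio.validate(table, meta, tax)
    sub = pp.subsample_counts(
        table, config.preprocess.subsample_depth, config.preprocess.seed
    )
    tio.write_count_table(sub, outdir / "subsampled.tsv")
    filtered = pp.prevalence_filter(
        sub,
        config.preprocess.filter_min_reads,
        config.preprocess.filter_min_samples,
    )
    tio.write_count_table(filtered, outdir / "filtered.tsv")
    # diversity on the subsampled table
    div = ds.sample_diversity(sub)
    _write(
        pd.DataFrame(
            {
                "sample_id": [d.sample_id for d in div],
                "richness": [d.richness for d in div],
                "shannon": [d.shannon for d in div],
            }
        ),
        outdir / "diversity.tsv",
        index=False,
    )
    # per-OTU compartment tests on the (relative) filtered table
    if filtered.shape[0]:
        anova = ds.per_otu_anova(
            pp.to_relative(filtered), meta, factor="compartment"
        )
        _write(
            ds.group_tests_to_frame(anova), outdir / "otu_anova.tsv",
            index=False,
        )
    hel = pp.hellinger_transform(sub)
    perm_rows = []
    for factor in ("compartment", "depth"):
        f_stat, p = ds.permanova(
            hel, meta, factor, config.permanova_n_perm, config.permanova_seed
        )
        perm_rows.append({"factor": factor, "pseudo_F": f_stat, "p": p})
    _write(pd.DataFrame(perm_rows), outdir / "permanova.tsv", index=False)
    # copy-number adjustment and qPCR correction when inputs allow
    if tax is not None and cn is not None:
        adjusted = pp.copy_number_adjust(sub, tax, cn)
        tio.write_count_table(
            tio.CountTable(adjusted.counts.round(6)), outdir / "adjusted.tsv"
        )
        if qpcr is not None:
            rows = [
                {
                    "sample_id": s,
                    "qpcr_total": qpcr[s],
                    "qpcr_corrected": pp.correct_qpcr_total(
                        float(qpcr[s]), sub, adjusted, s
                    ),
                }
                for s in sub.sample_ids
            ]
            _write(pd.DataFrame(rows), outdir / "qpcr_corrected.tsv", index=False)
    return {"subsampled": sub, "filtered": filtered, "meta": meta, "tax": tax}


@_run("network")
def stage_network(config: RunConfig, outdir: Path) -> net.CooccurrenceNetwork:
    filtered = tio.read_count_table(outdir / "filtered.tsv", "tsv")
    rel = pp.to_relative(filtered)
    rho = net.spearman_matrix(rel)
    p = net.reboot_pvalues(filtered, config.network.n_iter, config.network.seed)
    _write(rho, outdir / "rho.tsv")
    _write(p, outdir / "pvalues.tsv")
    thresholds = net.Thresholds(
        config.network.rho_pos, config.network.rho_neg, config.network.alpha
    )
    network = net.build_network(
        rho,
        p,
        thresholds,
        provenance={
            "n_iter": config.network.n_iter,
            "seed": config.network.seed,
            "rho_pos": thresholds.rho_pos,
            "rho_neg": thresholds.rho_neg,
            "alpha": thresholds.alpha,
        },
    )
    tio.write_edge_list(network.edges, outdir / "edges.tsv")
    tio.write_graphml(network.to_networkx(), outdir / "network.graphml")
    return network


def _load_network(outdir: Path) -> net.CooccurrenceNetwork:
    filtered = tio.read_count_table(outdir / "filtered.tsv", "tsv")
    edges_df = pd.read_csv(outdir / "edges.tsv", sep="\t")
    edges = [
        net.EdgeRecord(
            str(r.source), str(r.target), float(r.rho), float(r.p), str(r.sign)
        )
        for r in edges_df.itertuples()
    ]
    return net.CooccurrenceNetwork(filtered.otu_ids, edges)


@_run("cluster")
def stage_cluster(config: RunConfig, outdir: Path) -> ms.Partition:
    network = _load_network(outdir)
    pos = network.positive_subgraph()
    gray = sorted(set(network.nodes) - set(pos.nodes))
    (outdir / "gray_otus.txt").write_text("\n".join(gray) + "\n")
    if pos.number_of_nodes() == 0:
        raise ValueError("positive subgraph is empty; nothing to cluster")
    graph = ms.Graph.from_networkx(pos)
    mode = config.stability.mode
    if mode == "auto":
        mode = "exponential" if graph.n_nodes <= 2000 else "linearized"
    grid = np.logspace(
        np.log10(config.stability.t_min),
        np.log10(config.stability.t_max),
        config.stability.n_times,
    )
    result = ms.scan_markov_times(
        graph, grid, mode, config.stability.n_restarts, config.stability.seed
    )
    scan = pd.DataFrame(
        {
            "t": result.time_grid,
            "k": result.community_counts,
            "stability": result.stability,
        }
    )
    _write(scan, outdir / "stability_scan.tsv", index=False)
    partition = ms.select_partition(
        result, config.stability.k_min, config.stability.vi_tol
    )
    membership = pd.DataFrame(
        sorted(partition.as_dict().items()), columns=["otu_id", "community"]
    )
    _write(membership, outdir / "membership.tsv", index=False)
    return partition


def _load_partition(outdir: Path) -> ms.Partition:
    df = pd.read_csv(outdir / "membership.tsv", sep="\t", dtype=str)
    return ms.Partition(
        list(df["otu_id"]), df["community"].astype(int).to_numpy()
    )


@_run("core")
def stage_core(config: RunConfig, outdir: Path) -> dict:
    table, meta, tax, _, _ = _load_inputs(config, outdir)
    sub = tio.read_count_table(outdir / "subsampled.tsv", "tsv")
    partition = _load_partition(outdir)
    network = _load_network(outdir)
    results = {}
    for scope in ("all", "topsoil", "subsoil"):
        core = ca.scoped_core(sub, meta, scope, config.core_sd_rule)
        out = core.stats.copy()
        out["lineage"] = [
            ";".join(n for _, n in tax.classified_lineage(o))
            if tax is not None and o in tax.lineage.index
            else ""
            for o in out.index
        ]
        _write(out, outdir / f"core_{scope}.tsv")
        results[scope] = core
    attribution = ca.attribute_clusters(partition, sub, meta)
    attr = attribution.profiles.copy()
    attr["attributed_cell"] = [
        f"{d}:{c}" for d, c in (attribution.attribution[i] for i in attr.index)
    ]
    attr["tie"] = [i in attribution.ties for i in attr.index]
    attr.index.name = "community"
    _write(attr, outdir / "attribution.tsv")
    (outdir / "dendrogram_order.txt").write_text(
        "\n".join(attribution.dendrogram_order) + "\n"
    )
    neg = ca.cross_cluster_negative_table(network, partition, tax)
    _write(neg, outdir / "negative_correlations.tsv", index=False)
    _write(ca.shared_otu_summary(sub, meta), outdir / "shared_otus.tsv",
           index=False)
    results["attribution"] = attribution
    return results


@_run("ternary")
def stage_ternary(config: RunConfig, outdir: Path) -> None:
    _, meta, _, _, _ = _load_inputs(config, outdir)
    sub = tio.read_count_table(outdir / "subsampled.tsv", "tsv")
    for scope in ("topsoil", "subsoil"):
        points = ca.ternary_coordinates(
            sub, meta, scope, config.ternary_min_abundance
        )
        df = pd.DataFrame(
            [
                {
                    "otu_id": p.otu_id,
                    "bulk": p.bulk,
                    "drilosphere": p.drilosphere,
                    "rhizosphere": p.rhizosphere,
                    "total": p.total_abundance,
                }
                for p in points
            ],
            columns=["otu_id", "bulk", "drilosphere", "rhizosphere", "total"],
        )
        _write(df, outdir / f"ternary_{scope}.tsv", index=False)


@_run("report")
def stage_report(config: RunConfig, outdir: Path) -> dict:
    partition = _load_partition(outdir)
    network = _load_network(outdir)
    core_all = pd.read_csv(outdir / "core_all.tsv", sep="\t")
    sub = tio.read_count_table(outdir / "subsampled.tsv", "tsv")
    core = ca.core_microbiome(sub, _load_inputs(config, outdir)[1],
                              config.core_sd_rule)
    summary = {
        "n_otus_subsampled": int(sub.shape[0]),
        "n_otus_networked": len(network.nodes),
        "n_positive_edges": len(network.positive_edges()),
        "n_negative_edges": len(network.negative_edges()),
        "n_gray_otus": len(
            (outdir / "gray_otus.txt").read_text().split()
        ),
        "selected_k": partition.k,
        "core_size": len(core_all),
        "core_fraction_of_reads": core.fraction_of_reads,
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    if config.simulate is not None:
        stage_simulate(config, outdir)
    stage_preprocess(config, outdir)
    stage_network(config, outdir)
    stage_cluster(config, outdir)
    stage_core(config, outdir)
    stage_ternary(config, outdir)
    stage_report(config, outdir)
    return outdir
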