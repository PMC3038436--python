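"""Pipeline orchestration: ordered steps, logging, checkpoint/resume.

A run executes nine steps — qc, graph, sweep, filter, align, trim, concat,
models, trees — each reading its inputs and writing its products under the
run's output directory, so every step can also be invoked on its own
(through :mod:`minihal.cli`) given correctly formatted inputs.  A manifest
records the configuration, the seed and, per step, a content fingerprint
(SHA-256) of each declared output; a disrupted run restarts at the first
step whose products are missing or whose fingerprints no longer match, and
a completed resume is a no-op.  All randomness derives from the single
config seed, so an interrupted-and-resumed run is byte-identical to an
uninterrupted one.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path

import yaml

from . import mcl, models, njtree, ortho_filter, seqio, similarity, supermatrix, trim
from .supermatrix import TRIM_MODES

STEPS = ["qc", "graph", "sweep", "filter", "align", "trim", "concat", "models", "trees"]
MANIFEST = "manifest.json"
MAIN_LOG = "run.log"


@dataclasses.dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    hits_path: str | None = None  # default: <input_dir>/allvsall.tsv
    aligner: str = "builtin"
    inflations: tuple[float, ...] = mcl.DEFAULT_INFLATIONS
    min_taxon_fraction: float = 0.8
    min_alignment_length: int = 30
    trim_modes: tuple[str, ...] = TRIM_MODES
    tree_method: str = "nj"
    bootstrap_replicates: int = 100
    outgroup: str | None = None
    evalue_cutoff: float = similarity.DEFAULT_EVALUE_CUTOFF
    seed: int = 0
    keep_intermediates: bool = True

    def validate(self) -> None:
        if not Path(self.input_dir).is_dir():
            raise FileNotFoundError(f"input_dir {self.input_dir} does not exist")
        if not 0 < self.min_taxon_fraction <= 1:
            raise ValueError("min_taxon_fraction must lie in (0, 1]")
        bad = set(self.trim_modes) - set(TRIM_MODES)
        if bad:
            raise ValueError(f"unknown trim modes {sorted(bad)}")
        if Path(self.resolved_hits_path()).exists() is False:
            raise FileNotFoundError(f"hit table {self.resolved_hits_path()} not found")

    def resolved_hits_path(self) -> str:
        return self.hits_path or str(Path(self.input_dir) / "allvsall.tsv")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["inflations"] = list(self.inflations)
        d["trim_modes"] = list(self.trim_modes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["inflations"] = tuple(d.get("inflations", mcl.DEFAULT_INFLATIONS))
        d["trim_modes"] = tuple(d.get("trim_modes", TRIM_MODES))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    def __init__(self, outdir: Path, config: RunConfig):
        self.outdir = outdir
        self.data = {
            "version": 1,
            "config": config.to_dict(),
            "steps": {s: {"status": "pending", "outputs": {}} for s in STEPS},
        }

    @classmethod
    def load(cls, outdir: Path) -> "Manifest":
        with open(outdir / MANIFEST) as fh:
            data = json.load(fh)
        m = cls.__new__(cls)
        m.outdir = outdir
        m.data = data
        return m

    def save(self) -> None:
        with open(self.outdir / MANIFEST, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)

    def config(self) -> RunConfig:
        return RunConfig.from_dict(self.data["config"])

    def mark(self, step: str, status: str, outputs: list[Path] | None = None) -> None:
        entry = self.data["steps"][step]
        entry["status"] = status
        if outputs is not None:
            entry["outputs"] = {
                str(p.relative_to(self.outdir)): _sha256(p) for p in outputs
            }
        self.save()

    def verify(self, step: str) -> bool:
        entry = self.data["steps"][step]
        if entry["status"] != "done":
            return False
        for rel, digest in entry["outputs"].items():
            p = self.outdir / rel
            if not p.exists() or _sha256(p) != digest:
                return False
        return True


def _log(outdir: Path, message: str) -> None:
    stamp = datetime.datetime.now().isoformat(timespec="seconds")
    with open(outdir / MAIN_LOG, "a") as fh:
        fh.write(f"{stamp}\t{message}\n")


# ---------------------------------------------------------------------------
# step implementations (file in / file out)

def step_qc(cfg: RunConfig) -> list[Path]:
    out = Path(cfg.output_dir) / "qc"
    out.mkdir(parents=True, exist_ok=True)
    fastas = sorted(Path(cfg.input_dir).glob("*.fasta"))
    if not fastas:
        raise FileNotFoundError(f"no .fasta files in {cfg.input_dir}")
    pset = seqio.read_proteomes({p.stem: p for p in fastas})
    products = []
    for g in pset.genomes:
        p = out / f"{g}.fasta"
        seqio.write_fasta({r.alias: r.residues for r in pset.records[g]}, p)
        products.append(p)
    amap, qcr = out / "alias_map.tsv", out / "qc_report.tsv"
    seqio.write_alias_map(pset, amap)
    seqio.write_qc_report(pset, qcr)
    return products + [amap, qcr]


def _load_proteomes(cfg: RunConfig) -> seqio.ProteomeSet:
    out = Path(cfg.output_dir) / "qc"
    amap = seqio.read_alias_map(out / "alias_map.tsv")
    genomes = sorted({g for g, _ in amap.values()})
    records: dict[str, list[seqio.SequenceRecord]] = {g: [] for g in genomes}
    alias_map: dict[str, str] = {}
    for g in genomes:
        rows = seqio.read_fasta(out / f"{g}.fasta")
        for alias, residues in rows.items():
            header = amap[alias][1]
            records[g].append(seqio.SequenceRecord(header, alias, g, residues))
            alias_map[alias] = header
    return seqio.ProteomeSet(genomes, records, alias_map, [])


def step_graph(cfg: RunConfig) -> list[Path]:
    out = Path(cfg.output_dir) / "graph"
    out.mkdir(parents=True, exist_ok=True)
    pset = _load_proteomes(cfg)
    hits = similarity.parse_tabular_hits(
        cfg.resolved_hits_path(),
        alias_map=pset.alias_map,
        cutoff_evalue=cfg.evalue_cutoff,
    )
    graph = similarity.build_graph(hits, pset)
    weights = similarity.edge_weights(graph)
    p_nodes, p_best, p_w = out / "nodes.txt", out / "best_hits.tsv", out / "weights.tsv"
    with open(p_nodes, "w") as fh:
        fh.write("\n".join(graph.nodes) + "\n")
    with open(p_best, "w") as fh:
        fh.write("query\ttarget_genome\tsubject\n")
        for (q, g), s in sorted(graph.best_hits.items()):
            fh.write(f"{q}\t{g}\t{s}\n")
    with open(p_w, "w") as fh:
        fh.write("u\tv\tweight\n")
        for (u, v), w in sorted(weights.items()):
            fh.write(f"{u}\t{v}\t{w:.10g}\n")
    return [p_nodes, p_best, p_w]


def _load_graph(cfg: RunConfig) -> tuple[similarity.SimilarityGraph, dict]:
    out = Path(cfg.output_dir) / "graph"
    nodes = [l for l in (out / "nodes.txt").read_text().splitlines() if l]
    best: dict[tuple[str, str], str] = {}
    with open(out / "best_hits.tsv") as fh:
        next(fh)
        for line in fh:
            q, g, s = line.split()
            best[(q, g)] = s
    weights: dict[tuple[str, str], float] = {}
    with open(out / "weights.tsv") as fh:
        next(fh)
        for line in fh:
            u, v, w = line.split()
            weights[(u, v)] = float(w)
    pset = _load_proteomes(cfg)
    genome_of = {r.alias: r.genome_id for r in pset.all_records()}
    return similarity.SimilarityGraph(nodes, {}, best, genome_of), weights


def step_sweep(cfg: RunConfig) -> list[Path]:
    out = Path(cfg.output_dir) / "sweep"
    out.mkdir(parents=True, exist_ok=True)
    graph, weights = _load_graph(cfg)
    clusterings = mcl.inflation_sweep(weights, graph.nodes, cfg.inflations)
    products = []
    for c in clusterings:
        p = out / f"clusters_I{c.inflation}.txt"
        mcl.write_clusters(c, p)
        products.append(p)
    return products


def _load_sweep(cfg: RunConfig) -> list[mcl.Clustering]:
    out = Path(cfg.output_dir) / "sweep"
    clusterings = []
    for infl in cfg.inflations:
        p = out / f"clusters_I{infl}.txt"
        clusters = [
            frozenset(line.split("\t"))
            for line in p.read_text().splitlines()
            if line
        ]
        clusterings.append(mcl.Clustering(infl, clusters, 0, True))
    return clusterings


def step_filter(cfg: RunConfig) -> list[Path]:
    out = Path(cfg.output_dir) / "filter"
    out.mkdir(parents=True, exist_ok=True)
    pset = _load_proteomes(cfg)
    graph, _ = _load_graph(cfg)
    clusterings = _load_sweep(cfg)
    cs = ortho_filter.filter_sweep(clusterings, graph, pset, cfg.min_taxon_fraction)
    p_acc, p_rej = out / "clusters.tsv", out / "rejections.tsv"
    ortho_filter.write_cluster_table(cs, pset, p_acc)
    ortho_filter.write_rejection_log(cs, p_rej)
    return [p_acc, p_rej]


def _load_accepted(cfg: RunConfig) -> dict[str, list[str]]:
    """cluster_id -> member aliases, from the filter step's table."""
    out = Path(cfg.output_dir) / "filter" / "clusters.tsv"
    clusters: dict[str, list[str]] = {}
    with open(out) as fh:
        next(fh)
        for line in fh:
            cid, _infl, _g, alias, _h = line.rstrip("\n").split("\t", 4)
            clusters.setdefault(cid, []).append(alias)
    return clusters


def step_align(cfg: RunConfig) -> list[Path]:
    out = Path(cfg.output_dir) / "align"
    out.mkdir(parents=True, exist_ok=True)
    pset = _load_proteomes(cfg)
    by_alias = pset.by_alias()
    products = []
    for cid, aliases in sorted(_load_accepted(cfg).items()):
        named = [(a, by_alias[a].residues) for a in sorted(aliases)]
        aln = trim.align_cluster(cid, named, aligner=cfg.aligner)
        p = out / f"{cid}.fasta"
        seqio.write_alignment(aln.rows, p, "fasta")
        products.append(p)
    if not products:
        raise RuntimeError("no accepted clusters to align")
    return products


def step_trim(cfg: RunConfig) -> list[Path]:
    out = Path(cfg.output_dir) / "trim"
    out.mkdir(parents=True, exist_ok=True)
    products = []
    for p in sorted((Path(cfg.output_dir) / "align").glob("c*.fasta")):
        cid = p.stem
        aln = trim.ClusterAlignment(cid, seqio.read_alignment(p, "fasta"))
        for mode in cfg.trim_modes:
            trimmed = trim.trim_alignment(aln, mode)
            q = out / f"{cid}.{mode}.fasta"
            seqio.write_alignment(trimmed.rows, q, "fasta")
            products.append(q)
    return products


def _trimmed_alignments(cfg: RunConfig, mode: str) -> list[trim.ClusterAlignment]:
    out = Path(cfg.output_dir) / "trim"
    alns = []
    for p in sorted(out.glob(f"c*.{mode}.fasta")):
        cid = p.name.split(".")[0]
        alns.append(trim.ClusterAlignment(cid, seqio.read_alignment(p, "fasta")))
    return alns


def _genome_rows(aln: trim.ClusterAlignment, genome_of: dict[str, str]) -> trim.ClusterAlignment:
    rows = {
        supermatrix.sanitize_name(genome_of[a]): s for a, s in aln.rows.items()
    }
    return trim.ClusterAlignment(aln.cluster_id, rows)


def step_concat(cfg: RunConfig) -> list[Path]:
    out = Path(cfg.output_dir) / "concat"
    out.mkdir(parents=True, exist_ok=True)
    pset = _load_proteomes(cfg)
    genome_of = {r.alias: r.genome_id for r in pset.all_records()}
    taxa = [supermatrix.sanitize_name(g) for g in sorted(pset.genomes)]
    products = []
    for mode in cfg.trim_modes:
        alns = _trimmed_alignments(cfg, mode)
        alns = trim.min_length_filter(alns, cfg.min_alignment_length)
        if not alns:
            raise RuntimeError(
                f"no cluster alignment of mode {mode} survives the "
                f"minimum-length filter ({cfg.min_alignment_length})"
            )
        normed = [
            supermatrix.normalize(_genome_rows(a, genome_of), taxa) for a in alns
        ]
        sup = supermatrix.concatenate(normed, taxa, {}, mode)
        products.extend(supermatrix.write_supermatrix(sup, out / mode).values())
    return products


def _base_tree(rows: dict[str, str], model) -> njtree.PhyloTree:
    """NJ base tree under the given model (2-leaf tree below 3 taxa)."""
    present = {
        n: s for n, s in rows.items() if any(c not in "?-X" for c in s)
    }
    if len(present) < 3:
        names = list(present) or list(rows)[:2]
        t = njtree.ml_distance(rows[names[0]], rows[names[1]], model)
        root = njtree.Node(children=[
            njtree.Node(name=names[0], length=t / 2),
            njtree.Node(name=names[1], length=t / 2),
        ])
        return njtree.PhyloTree(root, rooted=True)
    dm = njtree.distance_matrix(present, model)
    return njtree.neighbor_joining(dm)


def step_models(cfg: RunConfig) -> list[Path]:
    out = Path(cfg.output_dir) / "models"
    out.mkdir(parents=True, exist_ok=True)
    jtt = models.load_model("JTT")
    products = []
    for mode in cfg.trim_modes:
        alns = _trimmed_alignments(cfg, mode)
        alns = trim.min_length_filter(alns, cfg.min_alignment_length)
        ranked: dict[str, list[models.ModelScore]] = {}
        for a in alns:
            tree = _base_tree(a.rows, jtt)
            ranked[a.cluster_id] = models.rank_models(a.rows, tree, a.cluster_id)
        best, tables, freq, one_model = models.summarize_models(ranked)
        p1, p2, p3 = (out / f"{mode}.best.tsv", out / f"{mode}.ranked.tsv",
                      out / f"{mode}.frequencies.tsv")
        models.write_best_models(best, p1)
        models.write_ranked_models(tables, p2)
        models.write_model_frequencies(freq, p3)
        # partition file with per-cluster assigned models
        pm = supermatrix.read_partition_file(
            Path(cfg.output_dir) / "concat" / f"{mode}.partitions.txt"
        )
        entries = [
            dataclasses.replace(e, model_name=best.get(e.cluster_id, one_model))
            for e in pm.entries
        ]
        p4 = out / f"{mode}.partitions.txt"
        supermatrix.write_partition_file(supermatrix.PartitionMap(entries), p4)
        p5 = out / f"{mode}.one_model.txt"
        p5.write_text(one_model + "\n")
        products += [p1, p2, p3, p4, p5]
    return products


def step_trees(cfg: RunConfig) -> list[Path]:
    out = Path(cfg.output_dir) / "trees"
    out.mkdir(parents=True, exist_ok=True)
    jtt = models.load_model("JTT")  # distance analysis: JTT, no rate variation
    outgroup = (
        supermatrix.sanitize_name(cfg.outgroup) if cfg.outgroup else None
    )
    products = []
    for i, mode in enumerate(cfg.trim_modes):
        sup = supermatrix.read_supermatrix(Path(cfg.output_dir) / "concat" / mode, mode)
        tree = njtree.bootstrap_consensus(
            sup.matrix, jtt, cfg.bootstrap_replicates,
            seed=cfg.seed + 1000 * (i + 1), outgroup=outgroup,
        )
        p = out / f"{mode}.nwk"
        p.write_text(tree.newick() + "\n")
        products.append(p)
    return products


_STEP_FUNCS = {
    "qc": step_qc,
    "graph": step_graph,
    "sweep": step_sweep,
    "filter": step_filter,
    "align": step_align,
    "trim": step_trim,
    "concat": step_concat,
    "models": step_models,
    "trees": step_trees,
}


def run(config: RunConfig, stop_after: str | None = None) -> Manifest:
    """Execute the pipeline in step order, fingerprinting each product."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(outdir, config)
    manifest.save()
    return _execute(manifest, config, start_index=0, stop_after=stop_after)


def _execute(
    manifest: Manifest, config: RunConfig, start_index: int, stop_after: str | None
) -> Manifest:
    outdir = Path(config.output_dir)
    for step in STEPS[start_index:]:
        manifest.mark(step, "running")
        _log(outdir, f"step {step} started")
        try:
            products = _STEP_FUNCS[step](config)
        except Exception as exc:
            manifest.mark(step, "pending")
            _log(outdir, f"step {step} FAILED: {exc}")
            raise
        manifest.mark(step, "done", products)
        _log(outdir, f"step {step} done ({len(products)} products)")
        if stop_after == step:
            break
    return manifest


def resume(output_dir: str | Path, aligner: str | None = None) -> Manifest:
    """Restart at the first step that is not done or whose outputs changed.

    Passing a different ``aligner`` invalidates the align step (and
    everything downstream), so a finished run can be re-analyzed with
    another alignment program without redoing clustering.
    """
    outdir = Path(output_dir)
    manifest = Manifest.load(outdir)
    config = manifest.config()
    if aligner is not None and aligner != config.aligner:
        config.aligner = aligner
        manifest.data["config"] = config.to_dict()
        for step in STEPS[STEPS.index("align"):]:
            manifest.mark(step, "pending")
    start = len(STEPS)
    for i, step in enumerate(STEPS):
        if not manifest.verify(step):
            start = i
            break
    if start == len(STEPS):
        _log(outdir, "resume: all steps complete, nothing to do")
        return manifest
    for step in STEPS[start:]:  # downstream steps re-run
        manifest.mark(step, "pending")
    _log(outdir, f"resume: restarting at step {STEPS[start]}")
    return _execute(manifest, config, start_index=start, stop_after=None)
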