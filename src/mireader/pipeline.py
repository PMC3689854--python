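"""End-to-end orchestration: training, de novo discovery, screening.

The working algorithm is: collapse reads to unique tags, assemble them into
contigs by exact suffix-prefix overlap, pair complementary contigs into
duplexes by global alignment with G:U wobble and free 3' overhangs, encode
each duplex over {M,X,I,D}, transform the encoding into positional
transition scores under length-clustered profiles, and classify with a
per-cluster MultiBoost ensemble of Best-First trees.  Training derives the
instances from reads mapped to reference pre-miRNA (positive) and other
ncRNA (negative) sets; discovery screens reads against known sequence sets
first and runs the assembled novel pool through the trained models.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import assembly, classify, duplex, io_reads, profiles as profiles_mod, quantify
from .parallel import parallel_map

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of every stage.

    ``provenance`` marks which defaults come from the source method
    description and which are artifact decisions.
    """

    # reads
    length_window: tuple[int, int] = (15, 35)
    max_mismatch_screen: int = 0
    min_reads_per_ref: int = 2
    # assembly
    min_overlap: int = 5
    max_contig_length: int = 80
    # duplex scoring
    match_score: float = 2.0
    wobble_score: float = 1.0
    mismatch_score: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    max_overhang: int = 2
    duplex_policy: str = "mutual"
    min_duplex_score: float = 0.0
    # profiles
    pseudocount: float = 0.5
    profile_mode: str = "conditional"
    min_cluster_support: int = 5
    cluster_length_band: int = 2
    # classifier
    K: int = 100
    min_leaf: int = 2
    max_expansions: int = 15
    min_cluster_instances: int = 40
    threshold_discover: float = 0.9
    threshold_eval: float = 0.5
    # iso-miR
    isomir_frac_threshold: float = 0.035
    isomir_max_subs: int = 2
    # run
    seed: int = 1
    workers: int = 1

    #: defaults stated by the source method (everything else is an artifact
    #: decision, exposed precisely because it is ours)
    provenance: tuple[str, ...] = (
        "min_overlap", "gap_open", "gap_extend", "max_overhang",
        "min_reads_per_ref", "threshold_discover", "isomir_frac_threshold",
        "isomir_max_subs", "K",
    )

    def scheme(self) -> duplex.ScoringScheme:
        return duplex.ScoringScheme(
            self.match_score, self.wobble_score, self.mismatch_score,
            self.gap_open, self.gap_extend, self.max_overhang,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["length_window"] = list(self.length_window)
        d["provenance"] = list(self.provenance)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "length_window" in d:
            d["length_window"] = tuple(d["length_window"])
        if "provenance" in d:
            d["provenance"] = tuple(d["provenance"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def write_manifest(
    outdir: str | Path,
    config: PipelineConfig,
    input_digests: dict[str, str],
) -> None:
    """Config hash, seed and input digests: enough to reproduce bit-exactly."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "inputs": input_digests,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)


def digest_sequences(seqs: Sequence[str]) -> str:
    h = hashlib.sha256()
    for s in seqs:
        h.update(s.encode())
        h.update(b"\n")
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainResult:
    profiles: dict[int, profiles_mod.TransitionProfileSet]
    models: dict[int, classify.MultiBoostModel]
    report: Optional[classify.EvaluationReport]
    counts: dict[str, int] = field(default_factory=dict)


def _cluster_instances(
    patterns: Sequence[str],
    labels: np.ndarray,
    profs: dict[int, profiles_mod.TransitionProfileSet],
    band: int,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Featurize patterns and group the vectors by representative cluster."""
    per: dict[int, tuple[list, list]] = {}
    for pat, lab in zip(patterns, labels):
        fv = profiles_mod.featurize(pat, profs, band)
        xs, ys = per.setdefault(fv.representative_profile, ([], []))
        xs.append(fv.values)
        ys.append(int(lab))
    return {
        L: (np.vstack(xs), np.array(ys)) for L, (xs, ys) in sorted(per.items())
    }


def _merge_small_clusters(
    data: dict[int, tuple[np.ndarray, np.ndarray]],
    min_instances: int,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Fold clusters below ``min_instances`` into the nearest-length cluster,
    padding or truncating feature vectors to the target width."""
    big = [L for L, (X, _) in data.items() if len(X) >= min_instances]
    if not big:
        target = max(data, key=lambda L: (len(data[L][0]), -L))
        big = [target]
    out: dict[int, tuple[list, list]] = {L: ([], []) for L in big}
    for L, (X, y) in data.items():
        tgt = L if L in out else min(big, key=lambda k: (abs(k - L), k))
        Xf = np.array([classify._fit_width(row, tgt) for row in X])
        out[tgt][0].append(Xf)
        out[tgt][1].append(y)
    return {
        L: (np.vstack(xs), np.concatenate(ys))
        for L, (xs, ys) in sorted(out.items())
    }


def train_from_patterns(
    patterns: Sequence[str],
    labels: Sequence[int],
    config: PipelineConfig = PipelineConfig(),
    seed: Optional[int] = None,
) -> TrainResult:
    """Train per-cluster models from encoded patterns with binary labels.

    Profiles are built from the positive patterns only; both classes are
    then featurized against them and a MultiBoost ensemble is trained per
    length cluster (small clusters fold into their nearest neighbour).
    """
    seed = config.seed if seed is None else seed
    labels = np.asarray(labels, int)
    pos = [duplex.EncodedPattern(p) for p, l in zip(patterns, labels) if l == 1]
    if not pos:
        raise ValueError("no positive patterns to build profiles from")
    profs = profiles_mod.build_profiles(
        pos, config.pseudocount, config.min_cluster_support, config.profile_mode
    )
    data = _cluster_instances(patterns, labels, profs, config.cluster_length_band)
    data = _merge_small_clusters(data, config.min_cluster_instances)
    models: dict[int, classify.MultiBoostModel] = {}
    for L, (X, y) in data.items():
        models[L] = classify.train_multiboost(
            X, y, K=config.K, seed=(seed * 1009 + L) % (2 ** 31 - 1),
            min_leaf=config.min_leaf, max_expansions=config.max_expansions,
        )
    return TrainResult(profs, models, None,
                       counts={f"cluster_{L}": len(data[L][0]) for L in data})


def predict_patterns(
    patterns: Sequence[str],
    profs: dict[int, profiles_mod.TransitionProfileSet],
    models: dict[int, classify.MultiBoostModel],
    band: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """(predicted classes, positive-class vote shares) for raw patterns."""
    preds, scores = [], []
    for pat in patterns:
        fv = profiles_mod.featurize(pat, profs, band)
        _, model = classify.route_to_model(fv.representative_profile, models)
        x = classify._fit_width(fv.values, model.n_features)
        votes = {0: 0.0, 1: 0.0}
        for tree, vw in zip(model.trees, model.vote_weights):
            votes[tree.predict_one(x)] += vw
        total = votes[0] + votes[1]
        share = votes[1] / total if total > 0 else 0.5
        cls, _ = model.predict_one(x)
        preds.append(cls)
        scores.append(share)
    return np.array(preds), np.array(scores)


def _assemble_reference_pool(args):
    """Assemble the reads of one reference and pair its contigs."""
    (ref_id, reads, min_overlap, max_len, scheme, policy, min_score) = args
    collapsed = io_reads.collapse_reads(reads)
    contigs = assembly.assemble(collapsed, min_overlap, max_len)
    ids = [f"{ref_id}.c{i}" for i in range(1, len(contigs) + 1)]
    dups, _ = duplex.select_duplexes(
        contigs, scheme, min_score=min_score, policy=policy, contig_ids=ids
    )
    return dups


def _instances_from_mapping(
    reads: Sequence[io_reads.Read],
    refset: io_reads.ReferenceSet,
    config: PipelineConfig,
) -> list[duplex.DuplexCandidate]:
    mapping = io_reads.map_reads_to_refs(reads, refset, max_mismatch=0)
    kept = io_reads.select_instance_refs(mapping, config.min_reads_per_ref)
    read_by_id = {r.id: r for r in reads}
    per_ref: dict[str, list[io_reads.Read]] = {r: [] for r in kept}
    for row in mapping.rows:
        if row.ref_id in per_ref:
            per_ref[row.ref_id].append(read_by_id[row.read_id])
    tasks = [
        (ref_id, per_ref[ref_id], config.min_overlap, config.max_contig_length,
         config.scheme(), config.duplex_policy, config.min_duplex_score)
        for ref_id in kept
    ]
    results = parallel_map(_assemble_reference_pool, tasks, config.workers)
    return [d for dups in results for d in dups]


def run_train(
    reads: Sequence[io_reads.Read],
    pre_mirna_refs: io_reads.ReferenceSet,
    ncrna_refs: io_reads.ReferenceSet,
    config: PipelineConfig = PipelineConfig(),
    outdir: Optional[str | Path] = None,
) -> TrainResult:
    """Build models from reads mapped onto reference sets.

    Reads mapping (exactly) to pre-miRNAs seed positive instances, reads
    mapping to other ncRNAs seed negatives; only references with two or more
    distinct mapped reads contribute.  Each reference's reads are assembled
    and its contigs paired into duplexes; encoded duplexes are split 50/50
    into train/held-out, profiles and per-cluster ensembles are trained, and
    the held-out half is scored.
    """
    if len(pre_mirna_refs) == 0 or len(ncrna_refs) == 0:
        raise ValueError("both reference sets must be non-empty")
    pos_dups = _instances_from_mapping(reads, pre_mirna_refs, config)
    neg_dups = _instances_from_mapping(reads, ncrna_refs, config)
    logger.info("instances: %d positive, %d negative duplexes",
                len(pos_dups), len(neg_dups))
    if not pos_dups or not neg_dups:
        raise ValueError(
            "could not form duplexes for both classes; check that references "
            "have >= 2 mapped reads each and contigs can pair"
        )
    patterns = [str(d.pattern) for d in pos_dups] + [str(d.pattern) for d in neg_dups]
    labels = np.array([1] * len(pos_dups) + [0] * len(neg_dups))
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(patterns))
    half = len(order) // 2
    tr, te = order[:half], order[half:]
    if len(set(np.array(labels)[tr])) < 2:
        raise ValueError("training split lost a class; provide more references")
    result = train_from_patterns(
        [patterns[i] for i in tr], labels[tr], config
    )
    if len(result.profiles) < 2:
        raise ValueError(
            "fewer than 2 length clusters with sufficient support; provide "
            "more references or lower min_cluster_support"
        )
    preds, scores = predict_patterns(
        [patterns[i] for i in te], result.profiles, result.models,
        config.cluster_length_band,
    )
    result.report = classify.evaluate_predictions(labels[te], preds, scores)
    result.counts.update(
        reads_in=len(reads),
        positive_duplexes=len(pos_dups),
        negative_duplexes=len(neg_dups),
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        profiles_mod.save_profiles(result.profiles, outdir / "profiles.json")
        classify.save_models(result.models, outdir / "models.json")
        with open(outdir / "report.json", "w") as fh:
            json.dump(result.report.to_dict(), fh, sort_keys=True, indent=1)
        write_manifest(outdir, config, {
            "reads": digest_sequences([r.sequence for r in reads]),
            "pre_mirna_refs": digest_sequences([r.sequence for r in pre_mirna_refs]),
            "ncrna_refs": digest_sequences([r.sequence for r in ncrna_refs]),
        })
    return result


# ---------------------------------------------------------------------------
# discovery


@dataclass
class DiscoveryReport:
    candidates: list[classify.DuplexCall]
    rejected: list[classify.DuplexCall]
    duplexes: list[duplex.DuplexCandidate]
    diagnostics: dict

    def candidate_ids(self) -> list[tuple[str, str]]:
        return [(c.top_id, c.bottom_id) for c in self.candidates]


def run_discover(
    reads: Sequence[io_reads.Read],
    profs: dict[int, profiles_mod.TransitionProfileSet],
    models: dict[int, classify.MultiBoostModel],
    config: PipelineConfig = PipelineConfig(),
    screen_refsets: Sequence[io_reads.ReferenceSet] = (),
    threshold: Optional[float] = None,
    outdir: Optional[str | Path] = None,
) -> DiscoveryReport:
    """De novo discovery: screen, collapse, assemble, pair, classify.

    Reads matching any screening set (priority order: known matures, other
    ncRNAs, transcriptome) are set aside; the novel pool is assembled into
    contigs, contigs are paired into duplexes, and each duplex is classified
    at ``threshold`` (default: the discovery cutoff 0.9).
    """
    threshold = config.threshold_discover if threshold is None else threshold
    total_copies = sum(r.count for r in reads)
    if screen_refsets:
        screen = io_reads.screen_reads(reads, screen_refsets,
                                       config.max_mismatch_screen)
        novel = screen.novel
        screen_totals = screen.totals
    else:
        novel = list(reads)
        screen_totals = {"novel": (len(novel), sum(r.count for r in novel))}
    collapsed = io_reads.collapse_reads(novel)
    contigs = assembly.assemble(collapsed, config.min_overlap,
                                config.max_contig_length)
    usable = [c for c in contigs if not c.flagged]
    ids = [f"contig{i}" for i in range(1, len(contigs) + 1)]
    dups, unpaired = duplex.select_duplexes(
        contigs, config.scheme(), min_score=config.min_duplex_score,
        policy=config.duplex_policy, contig_ids=ids, workers=config.workers,
    )
    diagnostics = {
        "reads_in": len(reads),
        "total_copies": total_copies,
        "unique_reads": len(collapsed),
        "contigs": len(contigs),
        "contigs_flagged": len(contigs) - len(usable),
        "duplex_candidates": len(dups),
        "unpaired_contigs": len(unpaired),
        "screen_totals": {k: list(v) for k, v in screen_totals.items()},
    }
    if not dups:
        logger.warning("no duplexes formed; diagnostics: %s", diagnostics)
        return DiscoveryReport([], [], [], diagnostics)
    calls = classify.classify_duplexes(dups, profs, models, threshold)
    candidates = [c for c in calls if c.is_mirna]
    rejected = [c for c in calls if not c.is_mirna]
    diagnostics["candidates"] = len(candidates)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        duplex.write_duplexes_tsv(dups, outdir / "duplexes.tsv")
        _write_calls(candidates, dups, total_copies, outdir / "candidates.tsv")
        _write_candidate_fasta(candidates, dups, outdir / "candidates.fasta")
        with open(outdir / "diagnostics.json", "w") as fh:
            json.dump(diagnostics, fh, sort_keys=True, indent=1)
        write_manifest(outdir, config,
                       {"reads": digest_sequences([r.sequence for r in reads])})
    return DiscoveryReport(candidates, rejected, dups, diagnostics)


def _write_calls(calls, dups, total_copies, path) -> None:
    by_pair = {(d.top_id, d.bottom_id): d for d in dups}
    with open(path, "w") as fh:
        fh.write("top_id\tbottom_id\tcluster\tscore\trscore\t"
                 "component_copies\texpression\n")
        for c in calls:
            copies = c.top_count + c.bottom_count
            expr = quantify.expression(copies, max(total_copies, 1))
            fh.write(f"{c.top_id}\t{c.bottom_id}\t{c.cluster}\t{c.score:.4f}\t"
                     f"{c.rscore:.4f}\t{copies}\t{expr:.6g}\n")


def _write_candidate_fasta(calls, dups, path) -> None:
    by_pair = {(d.top_id, d.bottom_id): d for d in dups}
    with open(path, "w") as fh:
        for c in calls:
            d = by_pair[(c.top_id, c.bottom_id)]
            top = d.aligned_top.replace(duplex.GAP, "")
            bottom = d.aligned_bottom.replace(duplex.GAP, "")[::-1]
            fh.write(f">{c.top_id} arm=5p score={c.score:.4f}\n{top}\n")
            fh.write(f">{c.bottom_id} arm=3p score={c.score:.4f}\n{bottom}\n")
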