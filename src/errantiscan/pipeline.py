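"""End-to-end composition of the simulation and analysis stages.

Each runner here is a thin, deterministic composition of library calls:
``run_pingpong`` (library simulation -> consensus mapping -> overlap
Z-score), ``run_census`` (genome simulation -> long reads -> detection ->
dedup -> novelty), and ``run_rnaseq`` (transcript mixture -> split-read
quantification).  ``run_pipeline`` ties them together under one config
with a stable report: every output carries the config hash and seed.

Seeds for the stages are spawned from the master seed with
``numpy.random.SeedSequence`` so stages stay independent yet fully
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import longread, rnaseq_quant, smallrna, synthetic_data
from .formats import SequenceRecord
from .longread import InsertionCall, CallRejection, InsertionLocus, TeConsensus
from .seedalign import SeedIndex

logger = logging.getLogger("errantiscan")

__all__ = [
    "RunConfig",
    "pingpong_analysis",
    "run_pingpong",
    "CensusResult",
    "run_census",
    "run_rnaseq",
    "run_pipeline",
]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """n child seeds below 2**31, deterministic in the master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# small RNA stage
# ---------------------------------------------------------------------------

def pingpong_analysis(
    reads: Sequence[SequenceRecord],
    te: TeConsensus,
    max_mismatches: int = 3,
    size_policy: smallrna.SizePolicy = smallrna.SizePolicy(),
) -> dict[str, Any]:
    """Size-select piRNAs, map them to the internal consensus and compute
    the ping-pong statistic.  Returns the histogram, result and counts."""
    bins = smallrna.classify_by_size(list(reads), size_policy)
    pirnas = bins["pirna"]
    placements = smallrna.map_reads(
        pirnas, te.internal, smallrna.MappingPolicy(max_mismatches=max_mismatches)
    )
    collapsed = smallrna.best_placements(placements)
    hist = smallrna.overlap_histogram(collapsed)
    result = smallrna.pingpong_zscore(hist)
    comp = smallrna.five_prime_base_composition(pirnas) if pirnas else {}
    return {
        "n_reads": len(reads),
        "n_pirna": len(pirnas),
        "n_sirna": len(bins["sirna"]),
        "n_placed": len(collapsed),
        "histogram": dict(hist.counts),
        "pct10": result.pct10,
        "zscore": result.zscore,
        "significant": result.significant,
        "five_prime_composition": comp,
    }


def run_pingpong(cfg: Mapping[str, Any], seed: int) -> dict[str, Any]:
    """Simulate a small-RNA library per ``cfg['smallrna']`` and analyse it."""
    te_seed, lib_seed = _spawn_seeds(seed, 2)
    te = synthetic_data.gen_te_consensus(seed=te_seed)
    sc = dict(cfg.get("smallrna", {}))
    params = synthetic_data.SmallRnaSimParams(
        n_reads=int(sc.get("n_reads", 20000)),
        sense_fraction=float(sc.get("sense_fraction", 0.5)),
        pp_fraction=float(sc.get("pp_fraction", 0.5)),
        u1_bias=float(sc.get("u1_bias", 0.75)),
        seed=lib_seed,
    )
    reads, truth = synthetic_data.gen_smallrna_library(te, params)
    out = pingpong_analysis(reads, te)
    out["n_truth_pairs"] = int(truth["partner_of"].notna().sum())
    return out


# ---------------------------------------------------------------------------
# long-read census stage
# ---------------------------------------------------------------------------

@dataclass
class CensusResult:
    te: TeConsensus
    sim: synthetic_data.SimulatedGenome
    reads: list[SequenceRecord]
    calls: list[InsertionCall]
    rejections: list[CallRejection]
    loci: list[InsertionLocus]
    score: dict

    def summary(self) -> dict[str, Any]:
        by_variant: dict[str, int] = {}
        for locus in self.loci:
            by_variant[locus.variant] = by_variant.get(locus.variant, 0) + 1
        return {
            "n_reads": len(self.reads),
            "n_calls": len(self.calls),
            "n_rejections": len(self.rejections),
            "n_loci": len(self.loci),
            "n_novel": sum(1 for l in self.loci if l.novelty == "new"),
            "n_shared": sum(1 for l in self.loci if l.novelty == "shared"),
            "loci_by_variant": by_variant,
            "score": {k: v for k, v in self.score.items() if k != "position_errors"},
        }


def detect_insertions(
    reads: Sequence[SequenceRecord],
    te: TeConsensus,
    genome: Sequence[SequenceRecord],
    catalog: longread.VariantCatalog | None = None,
    min_flank: int = 500,
    dedup_radius: int = 100,
) -> tuple[list[InsertionCall], list[CallRejection], list[InsertionLocus]]:
    """Full detection pass: hits -> chains -> deletions -> variant ->
    localization -> dedup.  ``genome`` is the insertion-free reference
    used for flank mapping."""
    catalog = catalog or longread.default_catalog()
    te_index = longread.build_te_index(te)
    genome_index = SeedIndex(list(genome))
    calls: list[InsertionCall] = []
    rejections: list[CallRejection] = []
    for read in reads:
        hits = te_index.hits(read)
        if not hits:
            continue
        for chain in longread.chain_hits(hits, internal_id=te.internal.id):
            if not chain.te_coverage:  # solo-LTR evidence, not an insertion call
                continue
            deletions = longread.infer_deletions(chain, te)
            variant = longread.classify_variant(deletions, chain, te, catalog)
            result = longread.locate_insertion(
                read, chain, genome_index,
                min_flank=min_flank, variant=variant, deletions=deletions,
            )
            if isinstance(result, CallRejection):
                rejections.append(result)
            else:
                calls.append(result)
    loci = longread.deduplicate_calls(calls, radius=dedup_radius)
    return calls, rejections, loci


def run_census(
    cfg: Mapping[str, Any],
    seed: int,
    verify_empty_sites: bool = False,
) -> CensusResult:
    """Simulate the configured genome + long reads and run detection.

    ``cfg`` follows the shipped fixture layout (genome, insertions,
    long_reads sections).  Empty-site verification is optional: simulated
    insertions are homozygous, so every locus is expected "absent".
    """
    te_seed, genome_seed, read_seed = _spawn_seeds(seed, 3)
    te = synthetic_data.gen_te_consensus(seed=te_seed)
    catalog = longread.default_catalog()
    gp = synthetic_data.genome_params_from_fixture(dict(cfg), seed=genome_seed)
    sim = synthetic_data.gen_genome_with_insertions(te, catalog, gp)
    lr = dict(cfg.get("long_reads", {}))
    reads, _read_truth = synthetic_data.gen_long_reads(
        sim.inserted,
        synthetic_data.LongReadSimParams(
            depth=float(lr.get("depth", 25)),
            length_mean=int(lr.get("length_mean", 12000)),
            length_sd=int(lr.get("length_sd", 6000)),
            subst_rate=float(lr.get("subst_rate", 0.02)),
            seed=read_seed,
        ),
    )
    calls, rejections, loci = detect_insertions(reads, te, sim.base, catalog)
    loci = longread.annotate_novelty(loci, sim.reference_annotation, family="ZAM")
    if verify_empty_sites:
        loci = [
            longread.InsertionLocus(
                chrom=l.chrom, position=l.position, variant=l.variant,
                supporting_reads=l.supporting_reads, novelty=l.novelty,
                empty_allele=longread.verify_empty_site(l, sim.base, list(reads)),
            )
            for l in loci
        ]
    score = synthetic_data.score_detection(loci, sim.truth)
    return CensusResult(
        te=te, sim=sim, reads=list(reads), calls=calls,
        rejections=rejections, loci=loci, score=score,
    )


# ---------------------------------------------------------------------------
# RNA-seq stage
# ---------------------------------------------------------------------------

def run_rnaseq(cfg: Mapping[str, Any], seed: int) -> dict[str, Any]:
    """Simulate the transcript mixture and quantify variant expression."""
    te_seed, rna_seed = _spawn_seeds(seed, 2)
    te = synthetic_data.gen_te_consensus(seed=te_seed)
    catalog = longread.default_catalog()
    rc = dict(cfg.get("rnaseq", {}))
    params = synthetic_data.RnaSeqSimParams(
        transcripts=rc.get("transcripts", {"fl": 1.0, "v2": 1.0, "control": 1.0}),
        read_length=int(rc.get("read_length", 150)),
        n_reads=int(rc.get("n_reads", 20000)),
        control_length=int(rc.get("control_length", 2000)),
        seed=rna_seed,
    )
    records, truth, _ref_lengths = synthetic_data.gen_spliced_rnaseq(te, catalog, params)
    dl, dr = longread.V2_BREAKPOINTS
    junction = rnaseq_quant.JunctionSpec(target_id=te.internal.id, left=dl, right=dr)
    expr = rnaseq_quant.variant_expression(
        records, junction, control=("pointed", (1, params.control_length))
    )
    return {
        "split_count": expr.split_count,
        "nonsplit_count": expr.nonsplit_count,
        "control_mean_coverage": expr.control_mean_coverage,
        "v_norm": expr.v_norm,
        "fl_norm": expr.fl_norm,
        "n_truth_junction_reads": int(truth["crosses_junction"].sum()),
    }


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """One reproducible end-to-end run.

    Stage sections absent from the config are skipped.
    """

    seed: int = 0
    outdir: Path = Path("results")
    stages: Mapping[str, Mapping[str, Any]] = field(default_factory=dict)
    verify_empty_sites: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        return cls(
            seed=int(d.get("seed", 0)),
            outdir=Path(d.get("outdir", "results")),
            stages={k: v for k, v in d.items()
                    if k in ("pingpong", "census", "rnaseq")},
            verify_empty_sites=bool(d.get("verify_empty_sites", False)),
            log_level=str(d.get("log_level", "INFO")),
        )


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {"seed": config.seed, "stages": {k: dict(v) for k, v in config.stages.items()},
         "verify_empty_sites": config.verify_empty_sites},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages in order and write a JSON report.

    A stage failure raises after logging the stage name; outputs written
    by earlier stages are retained.
    """
    logging.basicConfig(level=config.log_level)
    config.outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }
    for name, cfg in config.stages.items():
        logger.info("running stage %s", name)
        try:
            if name == "pingpong":
                report["stages"][name] = run_pingpong(cfg, config.seed)
            elif name == "census":
                result = run_census(cfg, config.seed, config.verify_empty_sites)
                report["stages"][name] = result.summary()
                loci_df = pd.DataFrame(
                    [
                        {"chrom": l.chrom, "position": l.position, "variant": l.variant,
                         "supporting_reads": l.supporting_reads, "novelty": l.novelty,
                         "empty_allele": l.empty_allele}
                        for l in result.loci
                    ]
                )
                loci_df.to_csv(config.outdir / "census_loci.tsv", sep="\t", index=False)
            elif name == "rnaseq":
                report["stages"][name] = run_rnaseq(cfg, config.seed)
            else:
                raise ValueError(f"unknown stage {name!r}")
        except Exception:
            logger.exception("stage %s failed", name)
            raise
    report_path = config.outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    return report
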