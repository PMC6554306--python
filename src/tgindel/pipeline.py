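"""End-to-end TgINDEL characterization: simulate -> align -> screen ->
junctions -> quant -> annotate -> report.

`run_pipeline` realizes a fixture (or takes an already-built one), maps the
simulated library with the built-in mapper, and produces the full report
plus all intermediate evidence, optionally writing the standard output
files (FASTA/FASTQ/truth JSON/report JSON/TSVs/junction FASTA) to a
directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import junctions as jx
from . import quant as qt
from . import report as rp
from . import screen as sc
from .align import PairedAlignments, build_index, map_pairs
from .fixtures import Fixture, build_fixture
from .reads import read_names, simulate_read_arrays, write_fastq_pair

log = logging.getLogger("tgindel")

K_MAIN = 31
K_CLIP = 15


@dataclass
class PipelineResult:
    fixture: Fixture
    paired: PairedAlignments
    classes: pd.DataFrame
    splits: pd.DataFrame
    clusters: list[jx.AnchorCluster]
    model: jx.InsertionModel
    deletion_call: qt.DeletionCall | None
    marker_counts: qt.MarkerCounts | None
    marker_cn: qt.CopyNumberEstimate | None
    depth_cn: qt.CopyNumberEstimate | None
    disruption: ann.DisruptionReport | None
    consensus: rp.ConsensusMonomer | None
    report: dict = field(default_factory=dict)


def _merge_junction_calls(calls: list[jx.JunctionCall], tol: int = 3) -> list[jx.JunctionCall]:
    """Collapse calls of one type/contig at the same breakpoint (within tol).

    Cluster-refined and split-discovered routes witness the same junction;
    the merged call keeps the strongest split evidence and the cluster's
    pair support.
    """
    merged: list[jx.JunctionCall] = []
    for call in sorted(calls, key=lambda c: (-c.split_support, -c.pair_support)):
        home = None
        for m in merged:
            if (
                m.type == call.type
                and m.ref_target == call.ref_target
                and m.ref_pos is not None
                and call.ref_pos is not None
                and abs(m.ref_pos - call.ref_pos) <= tol
            ):
                home = m
                break
        if home is None:
            merged.append(call)
        else:
            home.pair_support = max(home.pair_support, call.pair_support)
    return merged


def _select_insertion_pair(
    lefts: list[jx.JunctionCall], rights: list[jx.JunctionCall]
) -> tuple[jx.JunctionCall | None, jx.JunctionCall | None]:
    """Choose the coherent left/right junction pair delimiting the deletion.

    A valid pair sits on one contig with left < right; score favours total
    read support and resolved (split-confirmed) breakpoints.
    """

    def score(c: jx.JunctionCall) -> float:
        return c.split_support * 2 + c.pair_support + (5 if c.resolved else 0)

    best, best_score = None, -1.0
    for lc in lefts:
        for rc in rights:
            if lc.ref_target != rc.ref_target:
                continue
            if lc.ref_pos is None or rc.ref_pos is None or lc.ref_pos >= rc.ref_pos:
                continue
            s = score(lc) + score(rc)
            if s > best_score:
                best, best_score = (lc, rc), s
    if best:
        return best
    pick = lambda cs: max(cs, key=score) if cs else None
    return pick(lefts), pick(rights)


def run_pipeline(
    fixture,
    seed: int | None = None,
    outdir: str | Path | None = None,
    min_clip: int = sc.MIN_CLIP,
    min_cluster_support: int = jx.MIN_CLUSTER_SUPPORT,
    min_split: int = jx.MIN_SPLIT,
    context_bp: int = jx.CONTEXT_BP,
    score_truth: bool = True,
    use_fastq_roundtrip: bool = False,
) -> PipelineResult:
    """Run the whole characterization on a fixture (name, path, dict or
    built Fixture). With ``outdir`` the standard artifacts are written;
    ``use_fastq_roundtrip`` forces mapping to read the written FASTQ files
    rather than the in-memory read matrices (identical content)."""
    if not isinstance(fixture, Fixture):
        if seed is None:
            raise ValueError("seed required when building a fixture")
        fixture = build_fixture(fixture, seed)
    fx = fixture
    params = fx.read_params

    log.info("simulating %s reads (coverage %.1fx)", fx.name, params.coverage)
    r1, r2, meta = simulate_read_arrays(fx.haplotypes, params)
    names = read_names(meta, params.provenance_names)

    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        _write_fasta(out / "genome.fa", {
            f"{hap}|{contig}": seq
            for hap, contigs in fx.haplotypes.items()
            for contig, seq in contigs.items()
        })
        _write_fasta(out / "transgene_monomer.fa",
                     {fx.transgene_target: fx.monomer.sequence})
        if fx.vector_catalog:
            _write_fasta(out / "vector_catalog.fa", fx.vector_catalog)
        write_fastq_pair(r1, r2, names, out / "reads_R1.fastq", out / "reads_R2.fastq")
        fx.truth.to_json(out / "truth.json")

    index = build_index(fx.align_targets(), k=K_MAIN)
    log.info("mapping %d pairs", len(names))
    if use_fastq_roundtrip and out is not None:
        paired = map_pairs(out / "reads_R1.fastq", out / "reads_R2.fastq", index)
    else:
        paired = map_pairs(r1, r2, index, names=names)

    tg_targets = {fx.transgene_target}
    classes = sc.classify_pairs(paired, tg_targets, min_clip=min_clip)
    splits = sc.extract_split_reads(paired, min_clip=min_clip)
    clip_index = jx.build_clip_index(fx.clip_targets(), k=K_CLIP)
    splits = jx.remap_clips(splits, clip_index)
    endo = fx.truth.endogenous_locus
    if endo is not None and len(splits):
        shared_start, shared_end = fx.truth.shared_interval
        locus = (endo["start"], endo["start"] + (shared_end - shared_start))
        splits = jx.translate_shared_locus(
            splits,
            endo_tid=paired.index.names.index(endo["contig"]),
            endo_clip_tid=clip_index.names.index(endo["contig"]),
            locus=locus,
            mono_tid=paired.index.names.index(fx.transgene_target),
            mono_clip_tid=clip_index.names.index(fx.transgene_target),
            shared_start=shared_start,
        )

    clusters = jx.cluster_anchors(
        paired, classes, params.insert_mean, params.insert_sd,
        min_cluster_support=min_cluster_support,
    )
    tg_clip_tids = {
        i for i, n in enumerate(clip_index.names)
        if n in tg_targets or n in fx.vector_catalog
    }
    mono_main_tid = paired.index.names.index(fx.transgene_target)
    cluster_calls = [
        jx.refine_breakpoint(
            cl, splits, paired, clip_index, tg_clip_tids,
            insert_mean=params.insert_mean, insert_sd=params.insert_sd,
            context_bp=context_bp, min_split=min_split,
            tg_main_tids={mono_main_tid},
            ref_clip_tid=clip_index.names.index(cl.chrom),
        )
        for cl in clusters
    ]
    ref_tids = {
        i for i, n in enumerate(paired.index.names) if n != fx.transgene_target
    }
    discovered = jx.discover_split_junctions(
        splits, paired, tg_clip_tids, ref_tids,
        context_bp=context_bp, min_split=min_split,
    )
    calls = _merge_junction_calls(cluster_calls + discovered)
    model = jx.InsertionModel()
    model.left, model.right = _select_insertion_pair(
        [c for c in calls if c.type == "genome_tg_left"],
        [c for c in calls if c.type == "genome_tg_right"],
    )
    for which in ("left", "right"):
        if getattr(model, which) is None:
            model.notes.append(f"no {which} genome-transgene junction found")
    model.internal = jx.type_internal_junctions(
        paired, splits, clip_index, fx.transgene_target,
        fx.monomer.total_length, vector_targets=set(fx.vector_catalog),
        context_bp=context_bp, min_split=min_split,
    )

    # --- quantification
    deletion_call = marker_counts = marker_cn = depth_cn = None
    operator_sites = None
    iv = model.implied_deletion
    contig = fx.allele.chrom
    if iv is not None and model.left.ref_target == contig:
        ref_profile = qt.compute_depth(paired, contig, bin_size=500,
                                       read_length=params.read_length)
        deletion_call = qt.call_deletion(
            ref_profile, iv, exclude_bp=params.insert_mean)
        mono_profile = qt.compute_depth(paired, fx.transgene_target, bin_size=100,
                                        read_length=params.read_length)
        s, e = fx.monomer.shared_interval
        L = fx.monomer.total_length
        # trim one read length where a unique interval abuts the monomer
        # end: reads starting there cross a copy junction and register
        # their start on the far side, depressing start-counted depth
        unique_iv = [(0, s), (e, L - params.read_length)]
        unique_iv = [(a, b) for a, b in unique_iv if b - a >= 200]
        baseline_iv = [(0, max(0, iv[0] - params.insert_mean)),
                       (min(ref_profile.target_length, iv[1] + params.insert_mean),
                        ref_profile.target_length)]
        baseline_iv = [(a, b) for a, b in baseline_iv if b - a > 0]
        depth_cn = qt.copy_number_from_depth(
            mono_profile, ref_profile,
            tg_intervals=unique_iv, baseline_intervals=baseline_iv,
        )
        endo = fx.truth.endogenous_locus
        marker_counts = qt.count_marker_alleles(
            paired, fx.truth.markers, fx.transgene_target,
            endo["contig"] if endo else None,
        )
        marker_cn = qt.copy_number_from_markers(marker_counts)
        sites = int(fx.config.get("quant", {}).get("sites_per_monomer",
                                                   qt.SITES_PER_MONOMER))
        operator_sites = qt.count_operator_sites(marker_cn.rounded, sites)

    disruption = None
    if fx.transcripts and iv is not None:
        disruption = ann.build_disruption_report(
            fx.transcripts, iv, fx.annotation_contig or contig)

    consensus = None
    try:
        consensus = rp.build_consensus_monomer(
            paired, fx.transgene_target, fx.monomer.sequence)
    except ValueError:
        pass

    report = {}
    if iv is not None and deletion_call is not None:
        report = rp.assemble_report(
            model, deletion_call, marker_cn, depth_cn, marker_counts,
            operator_sites, disruption, consensus,
            truth=fx.truth if score_truth else None,
            meta={"fixture": fx.name, "seed": fx.truth.seed,
                  "n_pairs": int(len(names)), "coverage": params.coverage},
        )

    if out is not None and report:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)
        rp.junction_table(model).to_csv(out / "junctions.tsv", sep="\t", index=False)
        rp.junction_fasta(model, out / "junctions.fa")
        if marker_counts is not None:
            marker_counts.per_marker.to_csv(out / "marker_counts.tsv", sep="\t",
                                            index=False)
        ev = classes.copy()
        ev.insert(0, "read_id", paired.names)
        ev.to_csv(out / "pair_classes.tsv", sep="\t", index=False)
        if fx.transcripts:
            ann.write_gff3(fx.transcripts, out / "annotation.gff3")

    return PipelineResult(
        fixture=fx, paired=paired, classes=classes, splits=splits,
        clusters=clusters, model=model, deletion_call=deletion_call,
        marker_counts=marker_counts, marker_cn=marker_cn, depth_cn=depth_cn,
        disruption=disruption, consensus=consensus, report=report,
    )


def _write_fasta(path, records: dict[str, str], width: int = 80) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )
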