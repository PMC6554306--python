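"""Consensus monomer reconstruction and final TgINDEL report assembly."""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from ._seq import _BASES, encode
from .align import PairedAlignments
from .genome import TruthRecord
from .junctions import InsertionModel, JunctionCall


@dataclass
class ConsensusMonomer:
    sequence: str
    support: np.ndarray  # per-position pileup depth
    identity: float
    zero_coverage: np.ndarray  # positions that fell back to the reference base


def build_consensus_monomer(
    paired: PairedAlignments, monomer_target: str, monomer_reference: str
) -> ConsensusMonomer:
    """Per-position majority base over the monomer pileup.

    Ties and zero-coverage positions take the reference base (the latter
    are flagged). With an array of many near-identical copies the pileup is
    deep, so the majority vote wipes out independent sequencing errors.
    """
    tid = paired.index.names.index(monomer_target)
    L = len(monomer_reference)
    counts = np.zeros((L, 4), dtype=np.int64)
    any_read = False
    for mate in (1, 2):
        aln = paired.aln(mate)
        sel = np.flatnonzero(aln["tid"].to_numpy() == tid)
        if sel.size:
            any_read = True
        pos = aln["pos"].to_numpy()
        span = aln["span"].to_numpy()
        for row in sel:
            oriented = paired.oriented_read(mate, int(row))
            cl = int(aln["clip_left"].iat[int(row)])
            p0, s = int(pos[row]), int(span[row])
            hi = min(p0 + s, L)
            seg = oriented[cl : cl + (hi - p0)]
            ok = seg < 4
            np.add.at(counts, (np.arange(p0, hi)[ok], seg[ok]), 1)
    if not any_read:
        raise ValueError("no reads aligned to the monomer")

    ref_codes = encode(monomer_reference)
    best = counts.argmax(axis=1).astype(np.uint8)
    top = counts.max(axis=1)
    # tie -> reference base
    ref_count = counts[np.arange(L), np.minimum(ref_codes, 3)]
    tie = (ref_count == top) & (best != ref_codes)
    best[tie] = ref_codes[tie]
    zero = top == 0
    best[zero] = ref_codes[zero]
    seq = _BASES[best].tobytes().decode()
    identity = float((best == ref_codes).mean())
    return ConsensusMonomer(
        sequence=seq, support=counts.sum(axis=1), identity=identity, zero_coverage=zero
    )


REPORT_SCHEMA_RESOURCE = "data/report.schema.json"


def load_report_schema() -> dict:
    text = resources.files("tgindel").joinpath(REPORT_SCHEMA_RESOURCE).read_text()
    return json.loads(text)


def validate_report(report: dict, schema: dict | None = None) -> list[str]:
    """Minimal structural validation: required keys and primitive types."""
    schema = schema or load_report_schema()
    problems: list[str] = []

    def walk(node: dict, obj, path: str) -> None:
        for key, spec in node.get("required", {}).items():
            if key not in obj:
                problems.append(f"missing {path}{key}")
                continue
            val = obj[key]
            typ = spec.get("type")
            pytypes = {
                "object": dict, "array": list, "string": str,
                "number": (int, float), "integer": int, "boolean": bool,
            }
            if typ and not isinstance(val, pytypes[typ]):
                problems.append(f"{path}{key}: expected {typ}")
            elif typ == "object":
                walk(spec, val, f"{path}{key}.")

    walk(schema, report, "")
    return problems


def _junction_dict(j: JunctionCall) -> dict:
    return {
        "type": j.type,
        "ref_target": j.ref_target,
        "ref_pos": j.ref_pos,
        "tg_offset": j.tg_offset,
        "orientation": j.orientation,
        "split_support": int(j.split_support),
        "pair_support": int(j.pair_support),
        "resolved": bool(j.resolved),
        "junction_seq": j.junction_seq,
    }


def score_against_truth(report: dict, truth: TruthRecord) -> dict:
    """Scoring section comparing the calls with a simulation truth record."""
    deletion = report["deletion"]
    bp_err_left = bp_err_right = None
    if deletion["start"] is not None:
        bp_err_left = abs(int(deletion["start"]) - truth.canonical_start)
    if deletion["end"] is not None:
        bp_err_right = abs(int(deletion["end"]) - truth.canonical_end)
    called_types = {j["type"] for j in report["junctions"]}
    expected_internal = set()
    if truth.has_switch:
        expected_internal.add("tg_vector" if truth.spacer_length else "tg_head_to_head")
        if truth.spacer_length:
            expected_internal.add("vector_tg")
    # a head-to-tail seam exists iff either orientation block has >= 2 copies
    if max(truth.switch_index, truth.n_copies - truth.switch_index) >= 2:
        expected_internal.add("tg_head_to_tail")
    cn = report["copy_number"]
    return {
        "breakpoint_error_bp": {"left": bp_err_left, "right": bp_err_right},
        "deletion_length_error_bp": (
            None
            if deletion["length"] is None
            else int(deletion["length"]) - truth.canonical_deletion_length
        ),
        "zygosity_match": report["zygosity"] == truth.zygosity,
        "copy_number_error": {
            "marker": None if cn["marker"] is None else cn["marker"]["point"] - truth.n_copies,
            "depth": None if cn["depth"] is None else cn["depth"]["point"] - truth.n_copies,
        },
        "internal_junctions_missing": sorted(expected_internal - called_types),
    }


def assemble_report(
    model: InsertionModel,
    deletion_call,
    marker_cn,
    depth_cn,
    marker_counts,
    operator_sites: int | None,
    disruption,
    consensus: ConsensusMonomer | None,
    truth: TruthRecord | None = None,
    meta: dict | None = None,
) -> dict:
    """Assemble the one-document JSON TgINDEL report."""
    for name, part in (("junction model", model), ("deletion call", deletion_call)):
        if part is None:
            raise ValueError(f"mandatory report section missing: {name}")
    iv = model.implied_deletion
    report = {
        "meta": meta or {},
        "deletion": {
            "chrom": model.left.ref_target if model.left else None,
            "start": None if iv is None else iv[0],
            "end": None if iv is None else iv[1],
            "length": model.deletion_length,
            "depth_ratio": deletion_call.depth_ratio,
        },
        "zygosity": deletion_call.zygosity,
        "junctions": [_junction_dict(j) for j in model.junctions()],
        "orientation_switch": {
            "detected": bool(model.has_orientation_switch),
            "position_in_array_resolved": False,
        },
        "copy_number": {
            "marker": None
            if marker_cn is None
            else {
                "point": marker_cn.point,
                "rounded": marker_cn.rounded,
                "interval": list(marker_cn.interval),
                "pooled_transgene_reads": marker_counts.pooled_transgene,
                "pooled_endogenous_reads": marker_counts.pooled_endogenous,
                "pooled_ratio": marker_counts.pooled_ratio,
            },
            "depth": None
            if depth_cn is None
            else {
                "point": depth_cn.point,
                "rounded": depth_cn.rounded,
                "interval": list(depth_cn.interval),
            },
        },
        "operator_sites": operator_sites,
        "disruption": None
        if disruption is None
        else {
            "counts": disruption.counts,
            "per_gene": disruption.per_gene.to_dict("records"),
            "per_transcript": disruption.per_transcript.to_dict("records"),
        },
        "consensus_monomer": None
        if consensus is None
        else {
            "identity": consensus.identity,
            "mean_support": float(consensus.support.mean()),
            "zero_coverage_positions": int(consensus.zero_coverage.sum()),
        },
    }
    if truth is not None:
        report["scoring"] = score_against_truth(report, truth)
    problems = validate_report(report)
    if problems:
        raise ValueError(f"report failed schema validation: {problems}")
    return report


def junction_fasta(model: InsertionModel, path) -> None:
    """Write junction context sequences (primer-design ready) as FASTA."""
    with open(path, "w") as fh:
        seen: dict[str, int] = {}
        for j in model.junctions():
            if not j.junction_seq:
                continue
            n = seen.get(j.type, 0)
            seen[j.type] = n + 1
            name = j.type if n == 0 else f"{j.type}.{n + 1}"
            fh.write(f">{name}\n{j.junction_seq}\n")


def junction_table(model: InsertionModel) -> pd.DataFrame:
    return pd.DataFrame([_junction_dict(j) for j in model.junctions()])
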