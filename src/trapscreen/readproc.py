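"""Demultiplexing and junction validation of splinkerette reads.

Reads have a deterministic layout (barcode | TR tag | TTAA | flank), so
all checks are fixed-offset Hamming comparisons rather than alignments:
the barcode assigns the read to a clone or library, the terminal-repeat
tag confirms the amplicon, the target motif anchors the junction, and
whatever follows is the genomic flank passed to mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

__all__ = [
    "ProcessedRead",
    "ProcessingParams",
    "validate_manifest",
    "demultiplex",
    "trim_and_validate",
    "process_reads",
    "DISCARD_REASONS",
]

DISCARD_REASONS = ("none", "no_barcode", "no_tr_tag", "bad_junction", "flank_too_short")


@dataclass(frozen=True, slots=True)
class ProcessedRead:
    read_id: str
    sample_id: str | None
    flank: str
    junction_valid: bool
    discard_reason: str  # 'none' iff the read proceeds to mapping

    @property
    def passed(self) -> bool:
        return self.discard_reason == "none"


@dataclass(frozen=True)
class ProcessingParams:
    """Mismatch budgets for the fixed-layout checks."""

    barcode_mismatch: int = 1
    tag_mismatch: int = 2
    motif_mismatch: int = 1
    min_flank: int = 20
    tr_tag: str = "CGTCAGTCGAGC"
    motif: str = "TTAA"


def _hamming(a: str, b: str, limit: int) -> int:
    """Mismatch count with early exit once ``limit`` is exceeded."""
    if a == b:
        return 0
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def validate_manifest(manifest: dict[str, str], max_mismatch: int) -> int:
    """Check barcodes are one length with pairwise distance > 2*max_mismatch.

    That spacing guarantees at most one barcode lies within the mismatch
    budget of any read prefix, so assignment is never ambiguous. Returns
    the barcode length.
    """
    if not manifest:
        raise ValueError("empty barcode manifest")
    codes = list(manifest.values())
    lengths = {len(c) for c in codes}
    if len(lengths) != 1:
        raise ValueError("barcodes must share one length")
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate barcodes in manifest")
    need = 2 * max_mismatch
    for i in range(len(codes)):
        for j in range(i + 1, len(codes)):
            d = _hamming(codes[i], codes[j], need)
            if d <= need:
                raise ValueError(
                    f"barcodes {codes[i]} and {codes[j]} are {d} apart; "
                    f"need pairwise Hamming distance > {need} for "
                    f"max_mismatch={max_mismatch}"
                )
    return lengths.pop()


def demultiplex(
    reads: Iterable[tuple[str, str]],
    manifest: dict[str, str],
    max_mismatch: int = 1,
) -> Iterator[tuple[str, str, str | None]]:
    """Assign each (read_id, seq) to the unique barcode within budget.

    Yields (read_id, seq, sample_id or None). Exact prefix matches take a
    dictionary fast path; otherwise every barcode is scanned — by the
    manifest precondition at most one can be within ``max_mismatch``.
    """
    blen = validate_manifest(manifest, max_mismatch)
    exact = {bc: sid for sid, bc in manifest.items()}
    items = list(exact.items())
    for read_id, seq in reads:
        prefix = seq[:blen]
        sid = exact.get(prefix)
        if sid is None and max_mismatch > 0:
            for bc, cand in items:
                if _hamming(prefix, bc, max_mismatch) <= max_mismatch:
                    sid = cand
                    break
        yield read_id, seq, sid


def trim_and_validate(
    read_id: str,
    seq: str,
    sample_id: str | None,
    barcode_length: int,
    params: ProcessingParams,
) -> ProcessedRead:
    """Validate the TR tag and junction motif, strip them, keep the flank."""
    if sample_id is None:
        return ProcessedRead(read_id, None, "", False, "no_barcode")
    p = params
    t0 = barcode_length
    t1 = t0 + len(p.tr_tag)
    tag = seq[t0:t1]
    if len(tag) < len(p.tr_tag) or _hamming(tag, p.tr_tag, p.tag_mismatch) > p.tag_mismatch:
        return ProcessedRead(read_id, sample_id, "", False, "no_tr_tag")
    m1 = t1 + len(p.motif)
    mot = seq[t1:m1]
    if len(mot) < len(p.motif) or _hamming(mot, p.motif, p.motif_mismatch) > p.motif_mismatch:
        return ProcessedRead(read_id, sample_id, "", False, "bad_junction")
    flank = seq[m1:]
    if len(flank) < p.min_flank:
        return ProcessedRead(read_id, sample_id, flank, True, "flank_too_short")
    return ProcessedRead(read_id, sample_id, flank, True, "none")


def process_reads(
    reads: Iterable[tuple[str, str]],
    manifest: dict[str, str],
    params: ProcessingParams = ProcessingParams(),
    max_mismatch: int = 1,
) -> tuple[list[ProcessedRead], dict[str, int], dict[str, int]]:
    """Demultiplex + trim in one pass.

    Returns (passed reads, discard counts by reason incl. 'none', read
    counts per sample among passed reads). Counts conserve the input:
    sum over reasons equals the number of input reads.
    """
    blen = validate_manifest(manifest, max_mismatch)
    counts = {r: 0 for r in DISCARD_REASONS}
    per_sample: dict[str, int] = {sid: 0 for sid in manifest}
    passed: list[ProcessedRead] = []
    for read_id, seq, sid in demultiplex(reads, manifest, max_mismatch):
        pr = trim_and_validate(read_id, seq, sid, blen, params)
        counts[pr.discard_reason] += 1
        if pr.passed:
            passed.append(pr)
            per_sample[pr.sample_id] += 1
    return passed, counts, per_sample
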