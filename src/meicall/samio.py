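"""SAM/BAM input and output for ME-annotated alignments.

The ME mate annotation travels in a custom optional tag (``ZM``),
string-encoded as ``family,strand,offset,mate_mapq,hit_count`` on the
genome-anchored read, describing its consensus-mapped mate.  This is the
package's own documented dialect standing in for mapper-specific mate
annotation tags.

Reading supports multiple coordinate-sorted files merged into one
coordinate-ordered stream, and regional access through the index when a
region is requested.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple, Union

import pysam

from .model import AlignedRead, MEAnnotation, ReadPair

ME_TAG = "ZM"

logger = logging.getLogger(__name__)


def _parse_region(region: Optional[str]) -> Tuple[Optional[str], Optional[int], Optional[int]]:
    """``chrom:start-end`` with 1-based inclusive coordinates."""
    if region is None:
        return None, None, None
    if ":" not in region:
        return region, None, None
    chrom, span = region.rsplit(":", 1)
    start_s, end_s = span.replace(",", "").split("-")
    return chrom, int(start_s), int(end_s)


def _to_aligned_read(
    rec: pysam.AlignedSegment, rg_library: Dict[str, str], rg_sample: Dict[str, str]
) -> AlignedRead:
    ann = None
    if rec.has_tag(ME_TAG):
        try:
            ann = MEAnnotation.from_tag(str(rec.get_tag(ME_TAG)))
        except (ValueError, KeyError) as exc:
            warnings.warn(f"read {rec.query_name}: malformed {ME_TAG} tag dropped ({exc})")
    rg = str(rec.get_tag("RG")) if rec.has_tag("RG") else "lib0"
    return AlignedRead(
        name=rec.query_name,
        chrom=None if rec.is_unmapped else rec.reference_name,
        pos=None if rec.is_unmapped else rec.reference_start,
        cigar=rec.cigarstring or "",
        seq=rec.query_sequence or "",
        mapq=rec.mapping_quality,
        strand="-" if rec.is_reverse else "+",
        me_annotation=ann,
        library_id=rg_library.get(rg, rg),
        sample_id=rg_sample.get(rg, "sample0"),
    )


def read_alignments(
    paths: Union[str, Sequence[str]],
    region: Optional[str] = None,
) -> Iterator[AlignedRead]:
    """Stream alignments from one or more SAM/BAM files in coordinate order.

    Multiple files are merged into a single coordinate-sorted stream.
    Regional access (``chrom:start-end``, 1-based inclusive) requires an
    index for BAM input and raises if none can be used.
    """
    if isinstance(paths, str):
        paths = [paths]
    chrom, start, end = _parse_region(region)

    streams = []
    handles = []
    for path in paths:
        fh = pysam.AlignmentFile(path, "r" if str(path).endswith(".sam") else "rb",
                                 check_sq=False)
        handles.append(fh)
        rg_library, rg_sample = _read_groups(fh)
        if chrom is not None:
            try:
                it = fh.fetch(
                    chrom,
                    (start - 1) if start else None,
                    end,
                )
            except ValueError as exc:
                raise ValueError(
                    f"regional access to {path} requires a coordinate-sorted, "
                    f"indexed file: {exc}"
                ) from exc
        else:
            it = fh.fetch(until_eof=True)
        streams.append(_keyed(it, rg_library, rg_sample, len(streams)))

    last_key = None
    try:
        for key, _, _, read in heapq.merge(*streams):
            if last_key is not None and key < last_key:
                raise ValueError("input alignments are not coordinate-sorted")
            last_key = key
            yield read
    finally:
        for fh in handles:
            fh.close()


def _read_groups(fh: pysam.AlignmentFile) -> Tuple[Dict[str, str], Dict[str, str]]:
    rg_library: Dict[str, str] = {}
    rg_sample: Dict[str, str] = {}
    for rg in fh.header.to_dict().get("RG", []):
        rg_library[rg["ID"]] = rg.get("LB", rg["ID"])
        rg_sample[rg["ID"]] = rg.get("SM", "sample0")
    return rg_library, rg_sample


def _keyed(it, rg_library, rg_sample, stream_idx):
    for serial, rec in enumerate(it):
        if rec.is_secondary or rec.is_supplementary:
            continue
        key = (
            rec.reference_id if rec.reference_id >= 0 else 10**9,
            rec.reference_start if rec.reference_start >= 0 else 10**18,
        )
        yield key, stream_idx, serial, _to_aligned_read(rec, rg_library, rg_sample)


def write_alignments(
    reads: Iterable[AlignedRead],
    path: str,
    references: Dict[str, int],
    pair_index: Optional[Dict[str, Tuple[Optional[str], Optional[int]]]] = None,
) -> None:
    """Write reads to SAM (or BAM by extension) with read groups.

    ``references`` maps reference names to lengths.  Mate coordinates
    are filled from ``pair_index`` (name -> mate chrom/pos) when given.
    """
    ref_names = list(references)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": references[n]} for n in ref_names],
        "RG": [],
    }
    reads = list(reads)
    rgs = sorted({(r.library_id, r.sample_id) for r in reads})
    rg_ids = {}
    for lib, sample in rgs:
        rg_id = f"{sample}.{lib}"
        rg_ids[(lib, sample)] = rg_id
        header["RG"].append({"ID": rg_id, "LB": lib, "SM": sample})

    mode = "wb" if str(path).endswith(".bam") else "w"
    with pysam.AlignmentFile(path, mode, header=header) as out:
        tid = {n: i for i, n in enumerate(ref_names)}
        for r in sorted(
            reads, key=lambda x: (tid.get(x.chrom, 10**9), x.pos if x.pos is not None else 10**18)
        ):
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = r.name
            seg.query_sequence = r.seq
            seg.mapping_quality = r.mapq
            flag = 0
            if r.strand == "-":
                flag |= 0x10
            if not r.is_mapped:
                flag |= 0x4
            seg.flag = flag
            if r.is_mapped:
                seg.reference_id = tid[r.chrom]
                seg.reference_start = r.pos
                seg.cigarstring = r.cigar or f"{len(r.seq)}M"
            tags = [("RG", rg_ids[(r.library_id, r.sample_id)])]
            if r.me_annotation is not None:
                tags.append((ME_TAG, r.me_annotation.to_tag()))
            seg.set_tags(tags)
            if pair_index and r.name in pair_index:
                mchrom, mpos = pair_index[r.name]
                if mchrom is not None and mchrom in tid:
                    seg.next_reference_id = tid[mchrom]
                    seg.next_reference_start = mpos
            out.write(seg)


def write_pairs(pairs: Iterable[ReadPair], path: str, references: Dict[str, int]) -> None:
    """Write read pairs to SAM/BAM, placing unmapped mates at their anchor."""
    reads: List[AlignedRead] = []
    for p in pairs:
        a, b = p.mate_a, p.mate_b
        for mate, other in ((a, b), (b, a)):
            r = mate
            if not r.is_mapped and other.is_mapped:
                # SAM convention: unmapped mate placed at the anchor
                r = AlignedRead(
                    name=r.name, chrom=other.chrom, pos=other.pos, cigar="",
                    seq=r.seq, mapq=0, strand=r.strand,
                    me_annotation=r.me_annotation,
                    library_id=r.library_id, sample_id=r.sample_id,
                )
                r._placed_unmapped = True  # type: ignore[attr-defined]
            reads.append(r)
    ref_names = list(references)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": references[n]} for n in ref_names],
        "RG": [],
    }
    rgs = sorted({(r.library_id, r.sample_id) for r in reads})
    rg_ids = {}
    for lib, sample in rgs:
        rg_id = f"{sample}.{lib}"
        rg_ids[(lib, sample)] = rg_id
        header["RG"].append({"ID": rg_id, "LB": lib, "SM": sample})
    tid = {n: i for i, n in enumerate(ref_names)}

    def sort_key(r):
        return (tid.get(r.chrom, 10**9), r.pos if r.pos is not None else 10**18, r.name)

    mode = "wb" if str(path).endswith(".bam") else "w"
    with pysam.AlignmentFile(path, mode, header=header) as out:
        for r in sorted(reads, key=sort_key):
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = r.name
            seg.query_sequence = r.seq
            seg.mapping_quality = r.mapq
            flag = 0x1  # paired
            if r.strand == "-":
                flag |= 0x10
            unmapped = getattr(r, "_placed_unmapped", False) or not r.is_mapped
            if unmapped:
                flag |= 0x4
            seg.flag = flag
            if r.chrom is not None and r.pos is not None:
                seg.reference_id = tid[r.chrom]
                seg.reference_start = r.pos
                if not unmapped:
                    seg.cigarstring = r.cigar or f"{len(r.seq)}M"
            tags = [("RG", rg_ids[(r.library_id, r.sample_id)])]
            if r.me_annotation is not None:
                tags.append((ME_TAG, r.me_annotation.to_tag()))
            seg.set_tags(tags)
            out.write(seg)


def pair_up(reads: Iterable[AlignedRead]) -> Iterator[ReadPair]:
    """Group a read stream into pairs by name (order-insensitive)."""
    pending: Dict[str, AlignedRead] = {}
    for r in reads:
        mate = pending.pop(r.name, None)
        if mate is None:
            pending[r.name] = r
        else:
            yield ReadPair(mate, r)
    for leftover in pending.values():
        logger.debug("unpaired read %s dropped", leftover.name)
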