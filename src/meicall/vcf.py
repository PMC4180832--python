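"""VCF 4.2 output (and minimal input) for MEI calls.

POS is the 1-based breakpoint (last reference base before the
insertion, leftmost convention); ALT is the symbolic
``<INS:ME:FAMILY>``.  RP-only events carry a CIPOS confidence interval;
SR-resolved events report the breakpoint alone.  Per-sample fields are
GT and GL (log10 data likelihoods ordered REF/REF, REF/MEI, MEI/MEI).
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence

from .filters import EVIDENCE_RP_ONLY
from .genotype import GenotypeCall
from .model import MEFamily
from .pipeline import MEICall

_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">',
    '##INFO=<ID=MEFAMILY,Number=1,Type=String,Description="Mobile element family">',
    '##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="Confidence interval around POS (RP-only events)">',
    '##INFO=<ID=RP5,Number=1,Type=Integer,Description="Read-pair supporting fragments, 5-prime side">',
    '##INFO=<ID=RP3,Number=1,Type=Integer,Description="Read-pair supporting fragments, 3-prime side">',
    '##INFO=<ID=SR,Number=1,Type=Integer,Description="Split-read supporting fragments">',
    '##INFO=<ID=EVIDENCE,Number=1,Type=String,Description="Evidence class: RP_ONLY, SR_ONLY or RP_AND_SR">',
    '##INFO=<ID=MESTRAND,Number=1,Type=String,Description="Strand of the inserted element">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=GL,Number=G,Type=Float,Description="Log10 genotype likelihoods (REF/REF, REF/MEI, MEI/MEI)">',
]

_ALTS = [
    '##ALT=<ID=INS:ME:{fam},Description="{fam} mobile element insertion">'.format(
        fam=f.value
    )
    for f in MEFamily
]


def write_vcf(
    calls: Sequence[MEICall],
    path: str,
    reference: Mapping[str, str],
    sample_ids: Optional[Sequence[str]] = None,
    reference_name: str = "synthetic",
) -> None:
    """Write calls as VCF 4.2.  ``reference`` maps chrom -> sequence and
    supplies the REF base at POS and contig lengths.  Records must be
    position-sorted per chromosome."""
    if sample_ids is None:
        seen = []
        for c in calls:
            for s in c.genotypes:
                if s not in seen:
                    seen.append(s)
        sample_ids = sorted(seen) or ["sample0"]
    last: Dict[str, int] = {}
    for c in calls:
        if c.chrom in last and c.breakpoint < last[c.chrom]:
            raise ValueError("calls must be sorted by position within chromosomes")
        last[c.chrom] = c.breakpoint

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={reference_name}\n")
        for chrom, seq in reference.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        for line in _HEADER_LINES + _ALTS:
            fh.write(line + "\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for i, call in enumerate(calls):
            cand = call.candidate
            pos = cand.breakpoint
            ref_base = reference[cand.chrom][pos - 1] if cand.chrom in reference else "N"
            info = [
                "SVTYPE=INS",
                f"MEFAMILY={cand.family.value}",
                f"RP5={cand.rp_support_5p}",
                f"RP3={cand.rp_support_3p}",
                f"SR={cand.sr_support}",
                f"EVIDENCE={cand.evidence_class}",
            ]
            if cand.evidence_class == EVIDENCE_RP_ONLY:
                info.insert(2, f"CIPOS=0,{cand.ci_high - cand.ci_low}")
            if cand.me_strand:
                info.append(f"MESTRAND={cand.me_strand}")
            fields = [
                cand.chrom,
                str(pos),
                f"MEI_{i}",
                ref_base,
                f"<INS:ME:{cand.family.value}>",
                ".",
                "PASS",
                ";".join(info),
                "GT:GL",
            ]
            for s in sample_ids:
                gt = call.genotypes.get(s)
                fields.append(_format_sample(gt))
            fh.write("\t".join(fields) + "\n")


def _format_sample(gt: Optional[GenotypeCall]) -> str:
    if gt is None:
        return "./.:.,.,."
    gl = ",".join(f"{x:.4f}" for x in gt.log10_likelihoods)
    return f"{gt.gt}:{gl}"


def read_vcf(path: str) -> List[dict]:
    """Minimal reader for this module's records (evaluation plumbing).

    Returns dicts with chrom, pos, family, support counts, evidence and
    per-sample GT strings.
    """
    out: List[dict] = []
    samples: List[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.rstrip("\n").split("\t")[9:]
                continue
            parts = line.rstrip("\n").split("\t")
            info = dict(
                kv.split("=", 1) if "=" in kv else (kv, "")
                for kv in parts[7].split(";")
            )
            rec = {
                "chrom": parts[0],
                "pos": int(parts[1]),
                "id": parts[2],
                "alt": parts[4],
                "family": MEFamily(info["MEFAMILY"]),
                "rp5": int(info.get("RP5", 0)),
                "rp3": int(info.get("RP3", 0)),
                "sr": int(info.get("SR", 0)),
                "evidence": info.get("EVIDENCE", ""),
                "cipos": info.get("CIPOS"),
                "genotypes": {},
            }
            for s, field in zip(samples, parts[9:]):
                rec["genotypes"][s] = field.split(":")[0]
            out.append(rec)
    return out
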