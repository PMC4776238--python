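"""Minimal VCF 4.2 emission for panel calls.

SNVs and insertions are written as plain records; deletions (whose deleted
reference sequence the pileup summary does not carry) and copy-number
events use symbolic alleles (<DEL>/<DUP>) with an END, and fusions are
written as paired BND breakend records.  Positions convert from the
internal 0-based convention to VCF's 1-based here and only here.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from .caller import CNV, FUSION, VariantCall

_HEADER = """\
##fileformat=VCFv4.2
##source=oncopanel
##INFO=<ID=DP,Number=1,Type=Integer,Description="Quality-filtered depth">
##INFO=<ID=AO,Number=1,Type=Integer,Description="Alternate allele observations">
##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele fraction">
##INFO=<ID=PV,Number=1,Type=Float,Description="Binomial error-model tail p-value">
##INFO=<ID=END,Number=1,Type=Integer,Description="End of symbolic event">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">
##INFO=<ID=CN,Number=1,Type=Integer,Description="Copy-number estimate">
##INFO=<ID=GENE,Number=1,Type=String,Description="Panel gene">
##INFO=<ID=MATEID,Number=1,Type=String,Description="Breakend mate">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _basic_info(call: VariantCall) -> str:
    parts = [f"DP={call.depth}", f"AO={call.alt_count}", f"AF={call.vaf:.4f}",
             f"PV={call.p_value:.6g}"]
    if call.gene:
        parts.append(f"GENE={call.gene}")
    return ";".join(parts)


def _records(call: VariantCall, idx: int) -> list[str]:
    pos1 = call.pos + 1
    filt = call.filter
    if call.vtype == FUSION:
        mate_chrom = call.info.get("partner_chrom", call.chrom)
        mate_pos = call.info.get("partner_pos", call.pos) + 1
        a_id, b_id = f"bnd_{idx}a", f"bnd_{idx}b"
        alt_a = f"N]{mate_chrom}:{mate_pos}]"
        alt_b = f"N]{call.chrom}:{pos1}]"
        info_a = f"SVTYPE=BND;MATEID={b_id};{_basic_info(call)}"
        info_b = f"SVTYPE=BND;MATEID={a_id};GENE={call.info.get('partner_gene', '')}"
        return [
            f"{call.chrom}\t{pos1}\t{a_id}\tN\t{alt_a}\t.\t{filt}\t{info_a}",
            f"{mate_chrom}\t{mate_pos}\t{b_id}\tN\t{alt_b}\t.\t{filt}\t{info_b}",
        ]
    if call.vtype == CNV:
        end = call.info.get("end", call.pos + 1)
        alt = "<DUP>" if call.info.get("direction", "gain") == "gain" else "<DEL>"
        cn = call.info.get("copy_number", "")
        info = f"SVTYPE=CNV;END={end};CN={cn};{_basic_info(call)}"
        return [f"{call.chrom}\t{pos1}\t.\tN\t{alt}\t.\t{filt}\t{info}"]
    if call.alt.startswith("del"):
        length = int(call.alt[3:]) if call.alt[3:].isdigit() else len(call.alt) - 3
        info = f"SVTYPE=DEL;END={pos1 + length};{_basic_info(call)}"
        return [f"{call.chrom}\t{pos1}\t.\t{call.ref}\t<DEL>\t.\t{filt}\t{info}"]
    alt = call.ref + call.alt[3:] if call.alt.startswith("ins") else call.alt
    return [f"{call.chrom}\t{pos1}\t.\t{call.ref}\t{alt}\t.\t{filt}\t{_basic_info(call)}"]


def write_vcf(calls: Iterable[VariantCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER)
        for idx, call in enumerate(calls):
            for rec in _records(call, idx):
                fh.write(rec + "\n")
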