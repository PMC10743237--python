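"""Readers and writers binding the pipeline's file formats.

Variant calls serialize to VCF v4.2 (one file per sample) with INFO fields
VAF, DP, HETCLASS, VC and SM; filter flags travel in the FILTER column.
Insertions are left-anchored at their position; deletions anchor at the
preceding base, as VCF requires, so writing deletions needs the genome for
the deleted sequence. VAF survives the round trip at float32 precision
(the VCF Float width).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
import pysam

from .calling import Filter, HetClass, VarClass, VariantCall
from .errors import CoordinateError
from .reference import CircularGenome


def _vcf_header(genome_name: str, genome_length: int) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={genome_name},length={genome_length}>")
    header.add_line('##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">')
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Quality-passing depth">')
    header.add_line('##INFO=<ID=HETCLASS,Number=1,Type=String,Description="Heteroplasmy class">')
    header.add_line('##INFO=<ID=VC,Number=1,Type=String,Description="Variant class">')
    header.add_line('##INFO=<ID=SM,Number=1,Type=String,Description="Sample id">')
    for f in Filter:
        if f is not Filter.PASS:
            header.add_line(f'##FILTER=<ID={f.value},Description="Site filter {f.value}">')
    return header


def write_variants_vcf(
    calls: list[VariantCall], path: str | Path, genome: CircularGenome
) -> None:
    header = _vcf_header(genome.name, genome.length)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in sorted(calls, key=lambda c: (c.pos, c.alt)):
            if c.var_class is VarClass.SNV:
                pos, ref, alt = c.pos, c.ref, c.alt
            elif c.var_class is VarClass.INSERTION:
                pos, ref, alt = c.pos, c.ref, c.ref + c.alt[1:]
            else:
                if c.pos < 2:
                    raise CoordinateError(
                        "deletion at position 1 cannot be left-anchored in VCF"
                    )
                n = -c.indel_length
                anchor = genome.base(c.pos - 1)
                pos, ref, alt = c.pos - 1, anchor + genome.fetch(c.pos, n), anchor
            rec = vcf.new_record(
                contig=genome.name,
                start=pos - 1,
                alleles=(ref, alt),
                info={
                    "VAF": c.vaf,
                    "DP": c.depth,
                    "HETCLASS": c.het_class.value,
                    "VC": c.var_class.value,
                    "SM": c.sample_id,
                },
            )
            for f in sorted(c.filters, key=lambda f: str(f)):
                rec.filter.add(f.value if isinstance(f, Filter) else str(f))
            vcf.write(rec)


def read_variants_vcf(path: str | Path) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) == 1 and len(alt) == 1:
                var_class, pos, call_ref, call_alt = VarClass.SNV, rec.pos, ref, alt
            elif len(alt) > len(ref) == 1:
                var_class, pos = VarClass.INSERTION, rec.pos
                call_ref, call_alt = ref, "+" + alt[1:]
            elif len(ref) > len(alt) == 1:
                var_class, pos = VarClass.DELETION, rec.pos + 1
                call_ref, call_alt = ref[1], f"-{len(ref) - len(alt)}"
            else:
                raise ValueError(f"unsupported allele pair {ref}>{alt} at line for pos {rec.pos}")
            filters = set()
            tokens = list(rec.filter) or ["PASS"]
            for token in tokens:
                try:
                    filters.add(Filter(token))
                except ValueError:
                    warnings.warn(f"unknown FILTER token {token!r} preserved verbatim")
                    filters.add(token)
            calls.append(
                VariantCall(
                    sample_id=str(rec.info["SM"]),
                    pos=pos,
                    ref=call_ref,
                    alt=call_alt,
                    vaf=float(rec.info["VAF"]),
                    depth=int(rec.info["DP"]),
                    var_class=VarClass(rec.info["VC"]),
                    het_class=HetClass(rec.info["HETCLASS"]),
                    filters=frozenset(filters),
                )
            )
    return calls


def calls_to_frame(calls: list[VariantCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [c.sample_id for c in calls],
            "pos": [c.pos for c in calls],
            "ref": [c.ref for c in calls],
            "alt": [c.alt for c in calls],
            "vaf": [c.vaf for c in calls],
            "depth": [c.depth for c in calls],
            "var_class": [c.var_class.value for c in calls],
            "het_class": [c.het_class.value for c in calls],
            "filters": [
                ";".join(sorted(f.value if isinstance(f, Filter) else str(f) for f in c.filters))
                for c in calls
            ],
        }
    )


def write_calls_tsv(calls: list[VariantCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples(index=False):
        filters = frozenset(Filter(tok) for tok in str(r.filters).split(";"))
        out.append(
            VariantCall(
                sample_id=str(r.sample),
                pos=int(r.pos),
                ref=str(r.ref),
                alt=str(r.alt),
                vaf=float(r.vaf),
                depth=int(r.depth),
                var_class=VarClass(r.var_class),
                het_class=HetClass(r.het_class),
                filters=filters,
            )
        )
    return out
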