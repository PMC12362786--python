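"""Readers and writers for the package's interchange formats.

Variant catalogs round-trip as TSV (full fidelity) and as a minimal VCF
dialect (CHROM/POS/ID/REF/ALT plus INFO tags for gene, transcript, CDS/aa
position, consequence, per-source labels, allele counts and frequencies);
domains as BED-like TSV (0-based half-open aa coordinates on the protein);
transcripts as JSON (full fidelity, including the CDS sequence) and GFF3;
feature matrices and expression profiles as TSV with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .catalog import ConsequenceClass, VariantRecord
from .concordance import ExpressionProfile
from .prioritize import FeatureMatrix
from .simulate import DomainAnnotation
from .transcripts import TranscriptModel

# --------------------------------------------------------------------------
# variant TSV
# --------------------------------------------------------------------------

_VARIANT_COLUMNS = ["gene", "transcript_id", "chrom", "pos", "ref", "alt",
                    "consequence", "cds_pos", "aa_pos", "source_labels",
                    "allele_count", "allele_frequency", "inheritance", "extra"]


def _encode_map(d: dict) -> str:
    return ";".join(f"{k}:{v}" for k, v in sorted(d.items())) if d else "."


def _decode_map(s: str, cast=str) -> dict:
    if s in (".", "", None) or pd.isna(s):
        return {}
    out = {}
    for item in str(s).split(";"):
        k, v = item.split(":", 1)
        out[k] = cast(v)
    return out


def write_variants_tsv(records: Sequence[VariantRecord], path) -> None:
    rows = []
    for r in records:
        rows.append({
            "gene": r.gene, "transcript_id": r.transcript_id, "chrom": r.chrom,
            "pos": r.pos, "ref": r.ref, "alt": r.alt,
            "consequence": r.consequence.value if r.consequence else ".",
            "cds_pos": r.cds_pos if r.cds_pos is not None else ".",
            "aa_pos": r.aa_pos if r.aa_pos is not None else ".",
            "source_labels": _encode_map(r.source_labels),
            "allele_count": _encode_map(r.allele_count),
            "allele_frequency": _encode_map(
                {k: repr(v) for k, v in r.allele_frequency.items()}),
            "inheritance": r.inheritance or ".",
            "extra": json.dumps(r.extra, sort_keys=True) if r.extra else ".",
        })
    pd.DataFrame(rows, columns=_VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        records.append(VariantRecord(
            gene=row["gene"], transcript_id=row["transcript_id"],
            chrom=row["chrom"], pos=int(row["pos"]),
            ref=row["ref"], alt=row["alt"],
            consequence=(ConsequenceClass(row["consequence"])
                         if row["consequence"] != "." else None),
            cds_pos=int(row["cds_pos"]) if row["cds_pos"] != "." else None,
            aa_pos=int(row["aa_pos"]) if row["aa_pos"] != "." else None,
            source_labels=_decode_map(row["source_labels"]),
            allele_count=_decode_map(row["allele_count"], int),
            allele_frequency=_decode_map(row["allele_frequency"], float),
            inheritance=row["inheritance"] if row["inheritance"] != "." else None,
            extra=json.loads(row["extra"]) if row["extra"] != "." else {},
        ))
    return records


# --------------------------------------------------------------------------
# minimal VCF
# --------------------------------------------------------------------------

_VCF_INFO_HEADER = """\
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=TX,Number=1,Type=String,Description="Transcript identifier">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">
##INFO=<ID=CDSPOS,Number=1,Type=Integer,Description="1-based CDS position">
##INFO=<ID=AAPOS,Number=1,Type=Integer,Description="1-based protein position">
##INFO=<ID=SRC,Number=1,Type=String,Description="Source labels src|label&...">
##INFO=<ID=PAC,Number=1,Type=String,Description="Allele counts pop|n&...">
##INFO=<ID=PAF,Number=1,Type=String,Description="Allele frequencies pop|f&...">
##INFO=<ID=INH,Number=1,Type=String,Description="Inheritance mode">
"""


def _amp_encode(d: dict) -> Optional[str]:
    if not d:
        return None
    return "&".join(f"{k}|{str(v).replace(' ', '_')}" for k, v in sorted(d.items()))


def _amp_decode(s: Optional[str], cast=str) -> dict:
    if not s:
        return {}
    out = {}
    for item in s.split("&"):
        k, v = item.split("|", 1)
        out[k] = cast(v)
    return out


def write_vcf(records: Sequence[VariantRecord], path) -> None:
    contigs = sorted({r.chrom for r in records})
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append(_VCF_INFO_HEADER.rstrip("\n"))
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    ordered = sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    for r in ordered:
        info = [f"GENE={r.gene}", f"TX={r.transcript_id}"]
        if r.consequence:
            info.append(f"CSQ={r.consequence.value}")
        if r.cds_pos is not None:
            info.append(f"CDSPOS={r.cds_pos}")
        if r.aa_pos is not None:
            info.append(f"AAPOS={r.aa_pos}")
        src = _amp_encode(r.source_labels)
        if src:
            info.append(f"SRC={src}")
        pac = _amp_encode(r.allele_count)
        if pac:
            info.append(f"PAC={pac}")
        paf = _amp_encode({k: repr(v) for k, v in r.allele_frequency.items()})
        if paf:
            info.append(f"PAF={paf}")
        if r.inheritance:
            info.append(f"INH={r.inheritance}")
        lines.append("\t".join([r.chrom, str(r.pos), ".", r.ref, r.alt,
                                ".", ".", ";".join(info)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path) -> list[VariantRecord]:
    from cyvcf2 import VCF

    records = []
    for v in VCF(str(path)):
        records.append(VariantRecord(
            gene=v.INFO.get("GENE"), transcript_id=v.INFO.get("TX"),
            chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=v.ALT[0],
            consequence=(ConsequenceClass(v.INFO.get("CSQ"))
                         if v.INFO.get("CSQ") else None),
            cds_pos=v.INFO.get("CDSPOS"), aa_pos=v.INFO.get("AAPOS"),
            source_labels={k: val.replace("_", " ")
                           for k, val in _amp_decode(v.INFO.get("SRC")).items()},
            allele_count=_amp_decode(v.INFO.get("PAC"), int),
            allele_frequency=_amp_decode(v.INFO.get("PAF"), float),
            inheritance=v.INFO.get("INH"),
        ))
    return records


# --------------------------------------------------------------------------
# domains (BED-like, 0-based half-open on the protein)
# --------------------------------------------------------------------------

def write_domains_bed(domains: Sequence[DomainAnnotation], path) -> None:
    rows = [{"gene": d.gene, "start": d.start_aa - 1, "end": d.end_aa,
             "name": d.name, "dna_binding": int(d.dna_binding)}
            for d in domains]
    pd.DataFrame(rows, columns=["gene", "start", "end", "name",
                                "dna_binding"]).to_csv(path, sep="\t", index=False)


def read_domains_bed(path) -> list[DomainAnnotation]:
    df = pd.read_csv(path, sep="\t")
    return [DomainAnnotation(gene=row["gene"], name=row["name"],
                             start_aa=int(row["start"]) + 1,
                             end_aa=int(row["end"]),
                             dna_binding=bool(row["dna_binding"]))
            for _, row in df.iterrows()]


# --------------------------------------------------------------------------
# transcripts (JSON, GFF3)
# --------------------------------------------------------------------------

def write_transcripts_json(transcripts: Sequence[TranscriptModel], path) -> None:
    payload = [{
        "gene": t.gene, "transcript_id": t.transcript_id, "chrom": t.chrom,
        "strand": t.strand, "exons": [list(e) for e in t.exons],
        "cds_start": t.cds_start, "cds_end": t.cds_end,
        "cds_sequence": t.cds_sequence,
    } for t in transcripts]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_transcripts_json(path) -> list[TranscriptModel]:
    payload = json.loads(Path(path).read_text())
    return [TranscriptModel(
        gene=d["gene"], transcript_id=d["transcript_id"], chrom=d["chrom"],
        strand=d["strand"], exons=tuple(tuple(e) for e in d["exons"]),
        cds_start=d["cds_start"], cds_end=d["cds_end"],
        cds_sequence=d.get("cds_sequence")) for d in payload]


def write_transcripts_gff3(transcripts: Sequence[TranscriptModel], path) -> None:
    """GFF3 export (1-based inclusive); the CDS sequence is JSON-only."""
    lines = ["##gff-version 3"]
    for t in transcripts:
        attrs = f"ID={t.transcript_id};gene={t.gene}"
        lines.append("\t".join([t.chrom, "deafscape", "mRNA",
                                str(t.tx_start + 1), str(t.tx_end),
                                ".", t.strand, ".", attrs]))
        for i, (s, e) in enumerate(t.exons, 1):
            lines.append("\t".join([t.chrom, "deafscape", "exon",
                                    str(s + 1), str(e), ".", t.strand, ".",
                                    f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}"]))
        for i, (s, e) in enumerate(
                ((max(s, t.cds_start), min(e, t.cds_end)) for s, e in t.exons
                 if max(s, t.cds_start) < min(e, t.cds_end)), 1):
            lines.append("\t".join([t.chrom, "deafscape", "CDS",
                                    str(s + 1), str(e), ".", t.strand, "0",
                                    f"ID={t.transcript_id}.cds{i};Parent={t.transcript_id}"]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_transcripts_gff3(path) -> list[TranscriptModel]:
    mrnas: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _, ftype, start, end, _, strand, _, attrs = line.split("\t")
        fields = dict(a.split("=", 1) for a in attrs.split(";") if "=" in a)
        if ftype == "mRNA":
            mrnas[fields["ID"]] = {"gene": fields.get("gene", fields["ID"]),
                                   "chrom": chrom, "strand": strand,
                                   "exons": [], "cds": []}
        elif ftype in ("exon", "CDS"):
            parent = fields["Parent"]
            key = "exons" if ftype == "exon" else "cds"
            mrnas[parent][key].append((int(start) - 1, int(end)))
    out = []
    for tx_id, d in mrnas.items():
        cds = sorted(d["cds"])
        out.append(TranscriptModel(
            gene=d["gene"], transcript_id=tx_id, chrom=d["chrom"],
            strand=d["strand"], exons=tuple(sorted(d["exons"])),
            cds_start=cds[0][0], cds_end=cds[-1][1]))
    return out


# --------------------------------------------------------------------------
# feature matrices / expression
# --------------------------------------------------------------------------

def write_feature_matrix(features: FeatureMatrix, path) -> None:
    df = features.values.copy()
    df.insert(0, "label", features.labels)
    df.insert(1, "hidden_positive",
              [int(g in set(features.hidden_positive_genes)) for g in df.index])
    df.to_csv(path, sep="\t", index_label="gene")
    Path(str(path) + ".blocks").write_text(
        json.dumps(features.blocks, indent=0, sort_keys=True) + "\n")


def read_feature_matrix(path) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    labels = df.pop("label")
    hidden = list(df.index[df.pop("hidden_positive") == 1])
    blocks = json.loads(Path(str(path) + ".blocks").read_text())
    return FeatureMatrix(values=df, labels=labels, blocks=blocks,
                         hidden_positive_genes=hidden)


def write_expression_tsv(profile: ExpressionProfile, path) -> None:
    df = pd.DataFrame({"gene": profile.values.index,
                       "value": profile.values.to_numpy()})
    with open(path, "w") as fh:
        fh.write(f"# species={profile.species}\tscale={profile.scale}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_expression_tsv(path) -> ExpressionProfile:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        meta = dict(item.split("=", 1) for item in header.split("\t"))
        df = pd.read_csv(fh, sep="\t")
    return ExpressionProfile(meta["species"],
                             pd.Series(df["value"].to_numpy(), index=df["gene"]),
                             scale=meta["scale"])
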