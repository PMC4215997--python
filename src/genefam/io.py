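"""Readers and writers: packaged table fixtures, FASTA, gene coordinates.

The three packaged fixtures transcribe the published summary tables of the
soybean Cupin family verbatim: table1.tsv (69 family members with genomic
coordinates), table2.tsv (18 duplicate pairs with Ka/Ks and dates) and
table3.tsv (38 domestication-selected SNP sites with allele counts in 17
wild and 14 cultivated accessions).
"""

from __future__ import annotations

import logging
import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import DuplicatedBlock, DuplicatePair, GeneRecord, SnpSite

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

_CDS_ALPHABET = set("ACGTN")
_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")
_COUNT_PAIR_RE = re.compile(r"^(\d+)([A-Z])/(\d+)([A-Z])$")


def _fixture_path(name: str):
    return resources.files("genefam.data").joinpath(name)


def _read_fixture_tsv(name: str, path: Optional[PathLike]) -> pd.DataFrame:
    kwargs = dict(sep="\t", dtype=str, keep_default_na=False)
    if path is not None:
        return pd.read_csv(path, **kwargs)
    with resources.as_file(_fixture_path(name)) as p:
        return pd.read_csv(p, **kwargs)


def load_table1_fixture(path: Optional[PathLike] = None) -> list[GeneRecord]:
    """Load the 69 family-member records (or a table in the same dialect).

    Rows whose printed genomic span is too short for the stated peptide
    length are kept verbatim and reported with a warning; they reflect
    truncated coordinates in the source table, not parse errors.
    """
    df = _read_fixture_tsv("table1.tsv", path)
    required = {"gene_id", "locus", "chromosome", "start_raw", "end_raw",
                "aa_length", "n_exons"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            rec = GeneRecord(
                gene_id=row["gene_id"],
                locus=row["locus"],
                transcript=row.get("transcript", ""),
                chromosome=row["chromosome"],
                start_raw=int(row["start_raw"]),
                end_raw=int(row["end_raw"]),
                aa_length=int(row["aa_length"]),
                n_exons=int(row["n_exons"]),
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"gene table row {i + 2}: {exc}") from exc
        if not rec.span_consistent_with_protein():
            log.warning(
                "%s: printed span %d bp cannot hold %d aa; kept verbatim",
                rec.gene_id, rec.span_bp, rec.aa_length,
            )
        records.append(rec)
    return records


_MODE_ALIASES = {
    "fragment": "segmental", "segmental": "segmental",
    "tandem repeat": "tandem", "tandem": "tandem",
}
_FRAG_ALIASES = {"large": "large", "small": "small", "n/a": "n/a", "": "n/a"}


def load_table2_fixture(path: Optional[PathLike] = None) -> list[DuplicatePair]:
    """Load the 18 duplicate-pair rows, exactly as printed.

    The source table lists the Gmcupin3.1/Gmcupin19.13 pair twice; both
    rows are preserved so that printed aggregates can be reproduced.
    """
    df = _read_fixture_tsv("table2.tsv", path)
    pairs = []
    for i, row in df.iterrows():
        try:
            ks = float(row["ks"])
            ratio_txt = str(row.get("ratio", "")).strip()
            ratio = float(ratio_txt) if ratio_txt and ratio_txt.lower() != "n/a" else None
            pairs.append(DuplicatePair(
                gene_a=row["gene_a"],
                gene_b=row["gene_b"],
                mode=_MODE_ALIASES[str(row["mode"]).strip().lower()],
                fragment_class=_FRAG_ALIASES[str(row["fragment_class"]).strip().lower()],
                ka=float(row["ka"]),
                ks=ks,
                ratio=ratio,
                date_mya=float(row["date_mya"]),
            ))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"pair table row {i + 2}: {exc}") from exc
    return pairs


def parse_count_pair(text: str) -> dict[str, int]:
    """Parse the "11C/5T" allele-count dialect into an allele->count map."""
    m = _COUNT_PAIR_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed allele-count field {text!r}")
    c1, a1, c2, a2 = m.groups()
    if a1 == a2:
        raise ValueError(f"duplicate allele in {text!r}")
    return {a1: int(c1), a2: int(c2)}


def format_count_pair(counts: Mapping[str, int], order: Iterable[str]) -> str:
    return "/".join(f"{counts[a]}{a}" for a in order)


def load_table3_fixture(path: Optional[PathLike] = None) -> list[SnpSite]:
    """Load the 38 selected-site rows into :class:`SnpSite` records."""
    df = _read_fixture_tsv("table3.tsv", path)
    sites = []
    for i, row in df.iterrows():
        try:
            sites.append(SnpSite(
                gene_id=row["gene_id"],
                position=int(row["position"]),
                wild_counts=parse_count_pair(row["wild"]),
                cult_counts=parse_count_pair(row["cultivar"]),
            ))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"SNP table row {i + 2}: {exc}") from exc
    return sites


def write_gene_table(records: Iterable[GeneRecord], path: PathLike) -> None:
    rows = [{
        "gene_id": r.gene_id, "locus": r.locus, "transcript": r.transcript,
        "chromosome": r.chromosome, "start_raw": r.start_raw,
        "end_raw": r.end_raw, "aa_length": r.aa_length, "n_exons": r.n_exons,
    } for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_pair_table(pairs: Iterable[DuplicatePair], path: PathLike) -> None:
    rows = [{
        "gene_a": p.gene_a, "gene_b": p.gene_b,
        "mode": "Fragment" if p.mode == "segmental" else "Tandem Repeat",
        "fragment_class": p.fragment_class.capitalize() if p.fragment_class != "n/a" else "n/a",
        "ka": f"{p.ka:.4f}", "ks": f"{p.ks:.4f}",
        "ratio": f"{p.ratio:.4f}" if p.ratio is not None else "n/a",
        "date_mya": f"{p.date_mya:.2f}",
    } for p in pairs]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_snp_table(sites: Iterable[SnpSite], path: PathLike) -> None:
    rows = []
    for s in sites:
        order = sorted(s.wild_counts, key=lambda a: -s.wild_counts[a])
        rows.append({
            "gene_id": s.gene_id, "position": s.position,
            "wild": format_count_pair(s.wild_counts, order),
            "cultivar": format_count_pair(s.cult_counts, order),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fasta(path: PathLike, kind: str = "protein") -> dict[str, str]:
    """Read a FASTA file into an id->sequence map with alphabet validation.

    kind "cds" validates over ACGTN (case-insensitive); kind "protein"
    over the extended amino-acid alphabet including gaps stripped out.
    """
    if kind not in ("protein", "cds"):
        raise ValueError(f"unknown FASTA kind {kind!r}")
    alphabet = _CDS_ALPHABET if kind == "cds" else _PROTEIN_ALPHABET
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq.replace("-", "")) - alphabet
        if bad:
            raise ValueError(
                f"{rec.id}: illegal {kind} character(s) {sorted(bad)}"
            )
        out[rec.id] = seq
    return out


def write_fasta(seqs: Mapping[str, str], path: PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_gene_coords(path: PathLike, dialect: str = "gff3") -> list[GeneRecord]:
    """Read gene coordinates from GFF3 (gene features) or a 5+-column TSV.

    GFF3 coordinates are 1-based inclusive; strand comes from column 7.
    Non-gene feature lines are skipped (logged at debug level). The TSV
    dialect is the same one the packaged gene table uses.
    """
    if dialect == "tsv":
        return load_table1_fixture(path)
    if dialect != "gff3":
        raise ValueError(f"unknown coordinate dialect {dialect!r}")
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: GFF3 line has <9 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields[:9]
            if ftype != "gene":
                log.debug("%s:%d: skipping feature of type %s", path, lineno, ftype)
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_id = attr_map.get("ID") or attr_map.get("Name")
            if not gene_id:
                raise ValueError(f"{path}:{lineno}: gene feature without ID")
            start_i, end_i = int(start), int(end)
            if strand == "-":
                start_i, end_i = max(start_i, end_i), min(start_i, end_i)
            records.append(GeneRecord(
                gene_id=gene_id,
                locus=attr_map.get("locus", gene_id),
                chromosome=chrom,
                start_raw=start_i,
                end_raw=end_i,
                aa_length=int(attr_map.get("aa_length", 1)),
                n_exons=int(attr_map.get("n_exons", 1)),
            ))
    return records


def read_blocks(path: PathLike) -> list[DuplicatedBlock]:
    """Read duplicated-block annotations from TSV."""
    df = pd.read_csv(path, sep="\t")
    blocks = []
    for _, row in df.iterrows():
        span_a = (int(row["start_a"]), int(row["end_a"]))
        span_b = (int(row["start_b"]), int(row["end_b"]))
        length = int(row["length_bp"]) if "length_bp" in df.columns else max(
            span_a[1] - span_a[0] + 1, span_b[1] - span_b[0] + 1
        )
        blocks.append(DuplicatedBlock(
            block_id=str(row["block_id"]),
            chrom_a=row["chrom_a"], span_a=span_a,
            chrom_b=row["chrom_b"], span_b=span_b,
            length_bp=length,
        ))
    return blocks


def write_blocks(blocks: Iterable[DuplicatedBlock], path: PathLike) -> None:
    rows = [{
        "block_id": b.block_id,
        "chrom_a": b.chrom_a, "start_a": b.span_a[0], "end_a": b.span_a[1],
        "chrom_b": b.chrom_b, "start_b": b.span_b[0], "end_b": b.span_b[1],
        "length_bp": b.length_bp,
    } for b in blocks]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_vcf_sites(
    path: PathLike,
    wild_samples: Iterable[str],
    cult_samples: Iterable[str],
    gene_of_site=None,
) -> list[SnpSite]:
    """Build :class:`SnpSite` records from a VCF and two sample panels.

    Only biallelic SNPs are used; multiallelic or non-SNP records are
    skipped with a warning. Allele counts are over observed (non-missing)
    genotype calls in each panel. ``gene_of_site`` optionally maps
    (chrom, pos) to a gene id; by default the chromosome name is used.
    """
    from cyvcf2 import VCF

    wild_set, cult_set = list(wild_samples), list(cult_samples)
    vcf = VCF(str(path))
    samples = vcf.samples
    wild_idx = [samples.index(s) for s in wild_set]
    cult_idx = [samples.index(s) for s in cult_set]
    sites = []
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            log.warning("%s:%d skipped: not a biallelic SNP", var.CHROM, var.POS)
            continue
        ref, alt = var.REF, var.ALT[0]
        gts = var.genotypes  # [allele1, allele2, phased]

        def panel_counts(idx):
            counts = {ref: 0, alt: 0}
            for i in idx:
                for a in gts[i][:2]:
                    if a == 0:
                        counts[ref] += 1
                    elif a == 1:
                        counts[alt] += 1
            return counts

        gene = (
            gene_of_site(var.CHROM, var.POS) if gene_of_site else var.CHROM
        )
        sites.append(SnpSite(
            gene_id=gene, position=var.POS,
            wild_counts=panel_counts(wild_idx),
            cult_counts=panel_counts(cult_idx),
        ))
    return sites


def read_expression_tsv(path: PathLike, state: str = "raw_counts"):
    from .model import ExpressionMatrix
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=df, state=state)


def write_expression_tsv(matrix, path: PathLike) -> None:
    matrix.values.to_csv(path, sep="\t")
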