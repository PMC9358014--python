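"""Readers and writers for the plain-text formats the pipeline exchanges.

BED is 0-based half-open and carries the evidence class in the name column;
GFF3 is 1-based closed and converted to the in-memory 0-based convention on
read. Everything tabular goes through pandas.
"""

from __future__ import annotations

from typing import Iterable

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import AssemblySkeleton, ConfigError, EvidenceMarker, GeneModel, SyntenyBlock

SYNTENY_COLUMNS = ["species_a", "chrom_a", "start_a", "end_a",
                   "species_b", "chrom_b", "start_b", "end_b"]


# --- assembly skeleton -------------------------------------------------------

def write_skeleton(skeleton: AssemblySkeleton, path) -> None:
    rows = [(n, l, "chromosome") for n, l in skeleton.entries]
    rows += [(n, l, "unplaced") for n, l in skeleton.unplaced]
    pd.DataFrame(rows, columns=["name", "length", "placement"]).to_csv(
        path, sep="\t", index=False)


def read_skeleton(path) -> AssemblySkeleton:
    df = pd.read_csv(path, sep="\t")
    if "placement" not in df.columns:
        df["placement"] = "chromosome"
    entries = [(r["name"], int(r["length"])) for _, r in df.iterrows()
               if r["placement"] == "chromosome"]
    unplaced = [(r["name"], int(r["length"])) for _, r in df.iterrows()
                if r["placement"] != "chromosome"]
    return AssemblySkeleton(entries=entries, unplaced=unplaced)


# --- FASTA -------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta_lengths(path) -> dict[str, int]:
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def gc_fraction_from_fasta(path) -> float:
    """GC share over unambiguous bases only."""
    gc = at = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ConfigError("no unambiguous bases in FASTA")
    return gc / (gc + at)


# --- evidence BED ------------------------------------------------------------

def write_evidence_bed(markers: Iterable[EvidenceMarker], path) -> None:
    rows = sorted(((m.chrom, m.start, m.end, m.cls) for m in markers),
                  key=lambda r: (r[0], r[1], r[2]))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_evidence_bed(path) -> list[EvidenceMarker]:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "cls"])
    return [EvidenceMarker(cls=r.cls, chrom=r.chrom, start=int(r.start), end=int(r.end))
            for r in df.itertuples()]


# --- genotypes / sexes / marker map -----------------------------------------

def write_genotypes(genotypes: np.ndarray, marker_ids: list[str], path) -> None:
    pd.DataFrame(genotypes, columns=marker_ids).to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=np.int8), list(df.columns)


def write_sexes(sexes: np.ndarray, path) -> None:
    pd.DataFrame({"offspring": range(len(sexes)), "sex": sexes}).to_csv(
        path, sep="\t", index=False)


def read_sexes(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["sex"].to_numpy(dtype="U1")


def write_marker_map(marker_map: pd.DataFrame, path) -> None:
    marker_map.to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --- QTL records -------------------------------------------------------------

def write_qtl_table(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_qtl_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"lg", "position_cM", "lod", "pve_pct"} - set(df.columns)
    if missing:
        raise ConfigError(f"QTL table missing columns: {sorted(missing)}")
    return df


# --- DEG tables --------------------------------------------------------------

def write_deg_table(deg: pd.DataFrame, path) -> None:
    deg.to_csv(path, sep="\t", index=False)


def read_deg_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "log2fc"} - set(df.columns)
    if missing:
        raise ConfigError(f"DEG table missing columns: {sorted(missing)}")
    return df


# --- gene models: GFF3 + annotation TSV -------------------------------------

def write_gff3(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(f"{g.chrom}\tkaryoregion\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")


def write_annotation_table(genes: Iterable[GeneModel], path) -> None:
    rows = []
    for g in genes:
        go = ";".join(f"{term}|{cat}" for term, cat in sorted(g.go_terms))
        kegg = ";".join(sorted(g.kegg_pathways))
        rows.append((g.gene_id, g.nr_description, go, kegg))
    pd.DataFrame(rows, columns=["gene_id", "nr_description", "go_terms",
                                "kegg_pathways"]).to_csv(path, sep="\t", index=False)


def read_gene_models(gff3_path, annotation_path=None) -> list[GeneModel]:
    """Parse gene models from GFF3 (via gffutils), merging functional annotation."""
    db = gffutils.create_db(str(gff3_path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    annotations: dict[str, dict] = {}
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t").fillna("")
        for r in ann.itertuples():
            go = frozenset(tuple(item.split("|", 1)) for item in str(r.go_terms).split(";")
                           if item)
            kegg = frozenset(p for p in str(r.kegg_pathways).split(";") if p)
            annotations[r.gene_id] = {"nr_description": r.nr_description,
                                      "go_terms": go, "kegg_pathways": kegg}
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        extra = annotations.get(gene_id, {})
        genes.append(GeneModel(
            gene_id=gene_id, chrom=feat.seqid, start=feat.start - 1, end=feat.end,
            strand=feat.strand or ".", **extra))
    return genes


# --- synteny blocks ----------------------------------------------------------

def write_synteny_blocks(blocks: Iterable[SyntenyBlock], path) -> None:
    rows = [(b.species_a, b.chrom_a, b.start_a, b.end_a,
             b.species_b, b.chrom_b, b.start_b, b.end_b) for b in blocks]
    pd.DataFrame(rows, columns=SYNTENY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_synteny_blocks(path) -> list[SyntenyBlock]:
    df = pd.read_csv(path, sep="\t")
    missing = set(SYNTENY_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"synteny table missing columns: {sorted(missing)}")
    return [SyntenyBlock(r.species_a, r.chrom_a, int(r.start_a), int(r.end_a),
                         r.species_b, r.chrom_b, int(r.start_b), int(r.end_b))
            for r in df.itertuples()]
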