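"""File formats and annotation containers shared across the pipeline.

Coordinates are 0-based half-open everywhere in memory; GFF3 is converted
to/from its 1-based inclusive convention only at the file boundary.  BED is
0-based half-open and passes through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class Gene:
    """A gene model: span, strand and exon structure on one scaffold."""

    gene_id: str
    scaffold: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...] = ()

    @property
    def tss(self) -> int:
        """Transcription start: leftmost base on '+', rightmost on '-'."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class Transposon:
    te_id: str
    scaffold: str
    start: int
    end: int


# -- FASTA ------------------------------------------------------------------


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }


# -- GFF3 (genes with mRNA + exon children) ---------------------------------


def write_gff3(genes: list[Gene], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.scaffold}\tmethclone\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{g.scaffold}\tmethclone\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.scaffold}\tmethclone\texon\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.e{i};"
                    f"Parent={g.gene_id}.t1\n"
                )


def _gff_attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if "=" in part:
            key, value = part.split("=", 1)
            out[key] = value
    return out


def read_gff3(path) -> list[Gene]:
    genes: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            scaffold, _src, ftype, start, end, _score, strand, _fr, attrs = (
                cols[:9]
            )
            a = _gff_attrs(attrs)
            start0, end0 = int(start) - 1, int(end)
            if ftype == "gene":
                genes[a["ID"]] = {
                    "scaffold": scaffold,
                    "start": start0,
                    "end": end0,
                    "strand": strand,
                    "exons": [],
                }
            elif ftype == "mRNA":
                mrna_to_gene[a["ID"]] = a["Parent"]
            elif ftype == "exon":
                gene_id = mrna_to_gene.get(a["Parent"], a["Parent"])
                if gene_id in genes:
                    genes[gene_id]["exons"].append((start0, end0))
    return [
        Gene(
            gene_id=gid,
            scaffold=info["scaffold"],
            start=info["start"],
            end=info["end"],
            strand=info["strand"],
            exons=tuple(sorted(info["exons"])),
        )
        for gid, info in genes.items()
    ]


# -- BED --------------------------------------------------------------------


def write_bed(features: list[Transposon], path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.scaffold}\t{f.start}\t{f.end}\t{f.te_id}\n")


def read_bed(path) -> list[Transposon]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            cols = line.rstrip("\n").split("\t")
            name = cols[3] if len(cols) > 3 else f"feature_{i}"
            out.append(
                Transposon(
                    te_id=name,
                    scaffold=cols[0],
                    start=int(cols[1]),
                    end=int(cols[2]),
                )
            )
    return out


# -- gene -> GO annotation TSV ----------------------------------------------


def write_gene2go(annotations: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tgo_id\n")
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_gene2go(path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if header and not header.startswith("gene_id"):
            fh.seek(0)
        for line in fh:
            if not line.strip():
                continue
            gene, term = line.rstrip("\n").split("\t")[:2]
            out.setdefault(gene, set()).add(term)
    return out


# -- OBO (writer; parsing is done with obonet in go_enrichment) -------------


def write_obo(terms: dict[str, tuple[str, str, tuple[str, ...]]], path) -> None:
    """Write a minimal OBO file: id, name, namespace and is_a lines.

    ``terms`` maps term id -> (name, namespace, parent ids).
    """
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: methclone-synthetic\n")
        for term_id in sorted(terms):
            name, namespace, parents = terms[term_id]
            fh.write(f"\n[Term]\nid: {term_id}\nname: {name}\n")
            fh.write(f"namespace: {namespace}\n")
            for parent in parents:
                fh.write(f"is_a: {parent} ! {terms[parent][0]}\n")
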