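"""Reading and writing plastome records.

Two dialects are supported: FASTA + a GFF3 subset, and GenBank flat files
(via Biopython).  External coordinates are 1-based closed; internally
everything is 0-based half-open.  Origin-spanning features are written to
GFF3 with ``end`` extending past the sequence length (the common convention
for circular molecules) and read back as a single wrapped interval.
"""

from __future__ import annotations

import logging
from pathlib import Path

from Bio import SeqIO

from .records import (
    CircularSequence,
    CoordinateError,
    GeneFeature,
    ParseError,
    PlastomeRecord,
)

logger = logging.getLogger(__name__)

_GFF_KINDS = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "other": "gene"}
_GFF_KINDS_BACK = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "gene": "other"}


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path, is_circular: bool = True) -> CircularSequence:
    recs = list(SeqIO.parse(str(path), "fasta"))
    if not recs:
        raise ParseError(f"{path}: no FASTA records found")
    rec = recs[0]
    if len(recs) > 1:
        logger.warning("%s: %d FASTA records, using the first (%s)", path, len(recs), rec.id)
    return CircularSequence(str(rec.seq), name=rec.id, is_circular=is_circular)


def write_fasta(seq: CircularSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{seq.name}\n")
        for i in range(0, len(seq.residues), width):
            fh.write(seq.residues[i : i + width] + "\n")


# ---------------------------------------------------------------- GFF3

def read_gff3(path: str | Path, seq_len: int) -> list[GeneFeature]:
    features: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated columns")
            _, _, ftype, start_s, end_s, _, strand, _, attrs = cols
            if ftype == "region":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: strand must be + or -")
            name = _gff_attr(attrs, "gene") or _gff_attr(attrs, "ID") or f"feature{lineno}"
            start0 = start1 - 1
            end0 = end1
            if end0 > seq_len:  # circular convention: end past length wraps
                end0 -= seq_len
                if end0 > start0:
                    raise ParseError(f"{path}:{lineno}: wrapped feature longer than the genome")
            if start0 < 0 or start0 >= seq_len:
                raise CoordinateError(f"{path}:{lineno}: start {start1} outside sequence")
            features.append(
                GeneFeature(name=name, kind=_GFF_KINDS_BACK.get(ftype, "other"),
                            start=start0, end=end0, strand=strand)
            )
    return features


def _gff_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def write_gff3(record: PlastomeRecord, path: str | Path) -> None:
    n = len(record.sequence)
    name = record.sequence.name or "genome"
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {name} 1 {n}\n")
        fh.write(
            f"{name}\tplastokit\tregion\t1\t{n}\t.\t+\t.\t"
            f"ID={name};Is_circular={'true' if record.sequence.is_circular else 'false'}\n"
        )
        for f in record.features:
            end1 = f.end if not f.wraps else f.end + n
            fh.write(
                f"{name}\tplastokit\t{_GFF_KINDS[f.kind]}\t{f.start + 1}\t{end1}\t.\t"
                f"{f.strand}\t.\tID={f.name};gene={f.name}\n"
            )


# ---------------------------------------------------------------- GenBank

def read_genbank(path: str | Path) -> PlastomeRecord:
    try:
        rec = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises plain ValueError on bad input
        raise ParseError(f"{path}: not a parseable GenBank flat file: {exc}") from exc
    is_circular = rec.annotations.get("topology", "circular") == "circular"
    seq = CircularSequence(str(rec.seq), name=rec.id or rec.name, is_circular=is_circular)
    n = len(seq)
    features: list[GeneFeature] = []
    for feat in rec.features:
        if feat.type not in ("CDS", "tRNA", "rRNA"):
            continue
        name = (
            feat.qualifiers.get("gene", [None])[0]
            or feat.qualifiers.get("locus_tag", [None])[0]
            or feat.qualifiers.get("product", ["unnamed"])[0]
        )
        strand = "-" if feat.location.strand == -1 else "+"
        segs = [(int(p.start), int(p.end)) for p in feat.location.parts]
        if strand == "-":
            segs = segs[::-1]  # genome order regardless of strand
        if len(segs) == 2 and segs[0][1] == n and segs[1][0] == 0:
            # two pieces abutting the origin on a circle: one wrapped gene
            start, end = segs[0][0], segs[1][1]
            parts = None
        elif len(segs) == 1:
            (start, end), parts = segs[0], None
        else:
            start, end = segs[0][0], segs[-1][1]
            parts = tuple(segs)
        features.append(
            GeneFeature(name=name, kind=feat.type, start=start, end=end, strand=strand,
                        parts=parts)
        )
    return PlastomeRecord(sequence=seq, features=features, provenance=str(path))


# ---------------------------------------------------------------- dispatch

def read_plastome(path: str | Path, format: str, annotation: str | Path | None = None,
                  is_circular: bool = True) -> PlastomeRecord:
    """Read a plastome in one of the supported dialects.

    ``format`` is ``"fasta+gff3"`` (``path`` is the FASTA; ``annotation``
    defaults to the same stem with a ``.gff3`` suffix) or ``"genbank-flat"``.
    """
    path = Path(path)
    if format == "genbank-flat":
        return read_genbank(path)
    if format == "fasta+gff3":
        gff = Path(annotation) if annotation is not None else path.with_suffix(".gff3")
        seq = read_fasta(path, is_circular=is_circular)
        feats = read_gff3(gff, len(seq))
        return PlastomeRecord(sequence=seq, features=feats, provenance=f"{path}+{gff}")
    raise ParseError(f"unknown format {format!r}; use 'fasta+gff3' or 'genbank-flat'")


def write_plastome(record: PlastomeRecord, fasta_path: str | Path, gff3_path: str | Path) -> None:
    write_fasta(record.sequence, fasta_path)
    write_gff3(record, gff3_path)
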