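"""Genome database loading and canonicalization.

A genome database is a collection of m genomes, each one or more nucleotide
contigs carrying an integer genome ID (a flat taxonomic label -- genus,
species or strain, whatever rank the database was built at).  For indexing,
every genome is canonicalized into a single string that contains each contig
once forward and once reverse-complemented, with out-of-alphabet separator
sentinels between blocks, so that substring extraction can never cross a
contig or strand boundary.

Coordinates are 0-based half-open on the canonical text; reported loci
additionally carry contig index and strand.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO

#: Separator sentinel placed between blocks of the canonical text.  It never
#: matches a nucleotide, so no indexed substring can span it.
SEPARATOR = "#"

#: IUPAC nucleotide codes accepted on input.  Anything outside A/C/G/T is
#: retained in the canonical text but acts as a boundary character for
#: substring extraction, exactly like the separator.
IUPAC_CODES = "ACGTNRYSWKMBDHV"

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")
_IUPAC_SET = frozenset(IUPAC_CODES)

GENOME_DB_FORMAT_VERSION = "1"


class GenomeDBError(ValueError):
    """Raised for malformed genome database inputs."""


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N (and IUPAC ambiguity codes) map to
    their complement codes, so the involution rc(rc(s)) == s holds.

    Raises
    ------
    GenomeDBError
        If ``seq`` contains a character outside the IUPAC nucleotide codes.
    """
    s = seq.upper()
    bad = set(s) - _IUPAC_SET
    if bad:
        raise GenomeDBError(f"non-IUPAC nucleotide character(s): {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Block:
    """One contiguous nucleotide block of the canonical text.

    ``start``/``end`` are canonical-text coordinates; ``contig`` indexes into
    the record's contig list; ``strand`` is '+' for the forward copy and '-'
    for the reverse-complemented copy.
    """

    start: int
    end: int
    contig: int
    strand: str


@dataclass
class GenomeRecord:
    """One genome of the database in canonical indexing form."""

    genome_id: int
    name: str
    contigs: list[str]
    text: str = field(repr=False)
    genome_length: int
    blocks: list[Block] = field(repr=False)

    def to_forward_coords(self, pos: int, length: int) -> tuple[int, str, int]:
        """Map a canonical-text occurrence ``[pos, pos+length)`` to
        (contig index, strand, forward-strand start within the contig)."""
        for b in self.blocks:
            if b.start <= pos and pos + length <= b.end:
                off = pos - b.start
                if b.strand == "+":
                    return b.contig, "+", off
                clen = b.end - b.start
                return b.contig, "-", clen - off - length
        raise GenomeDBError(
            f"occurrence [{pos}, {pos + length}) crosses a block boundary "
            f"in genome {self.genome_id}"
        )


def _make_record(genome_id: int, name: str, contigs: Sequence[str]) -> GenomeRecord:
    ups = []
    for k, c in enumerate(contigs):
        c = c.upper()
        if not c:
            raise GenomeDBError(f"genome {genome_id} ({name}): contig {k} is empty")
        bad = set(c) - _IUPAC_SET
        if bad:
            raise GenomeDBError(
                f"genome {genome_id} ({name}): contig {k} has non-IUPAC "
                f"character(s) {sorted(bad)}"
            )
        ups.append(c)
    parts = list(ups) + [reverse_complement(c) for c in ups]
    text = SEPARATOR.join(parts)
    blocks: list[Block] = []
    pos = 0
    n = len(ups)
    for j, part in enumerate(parts):
        contig = j if j < n else j - n
        strand = "+" if j < n else "-"
        blocks.append(Block(pos, pos + len(part), contig, strand))
        pos += len(part) + 1  # skip separator
    return GenomeRecord(
        genome_id=genome_id,
        name=name,
        contigs=ups,
        text=text,
        genome_length=sum(len(c) for c in ups),
        blocks=blocks,
    )


@dataclass
class GenomeDB:
    """The indexed genome collection."""

    genomes: list[GenomeRecord]

    def __post_init__(self) -> None:
        ids = [g.genome_id for g in self.genomes]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise GenomeDBError(f"duplicate genome_id(s): {sorted(dup)}")
        self.id_to_record: dict[int, GenomeRecord] = {
            g.genome_id: g for g in self.genomes
        }

    @property
    def m(self) -> int:
        return len(self.genomes)

    def __iter__(self):
        return iter(self.genomes)


def db_from_sequences(
    named_contigs: Sequence[tuple[int, str, Sequence[str]]]
) -> GenomeDB:
    """Build a :class:`GenomeDB` directly from in-memory sequences.

    ``named_contigs`` holds (genome_id, name, contigs) triples.
    """
    return GenomeDB([_make_record(gid, name, ctgs) for gid, name, ctgs in named_contigs])


def load_genomes(
    fasta_paths: Sequence[str | os.PathLike],
    id_map: Mapping[str, int] | None = None,
) -> GenomeDB:
    """Load a genome database from FASTA files.

    Without ``id_map`` each file is one genome (all its records are contigs)
    and genome IDs are assigned 1..m in input order.  With ``id_map``, each
    FASTA record name (header up to first whitespace) is looked up to obtain
    its genome ID, and records sharing an ID are grouped into one genome.
    """
    if not fasta_paths:
        raise GenomeDBError("no FASTA files given")
    if id_map is None:
        records = []
        for k, path in enumerate(fasta_paths):
            contigs, names = _read_fasta(path)
            records.append(
                _make_record(k + 1, names[0] if names else Path(path).stem, contigs)
            )
        return GenomeDB(records)

    grouped: dict[int, tuple[str, list[str]]] = {}
    for path in fasta_paths:
        contigs, names = _read_fasta(path)
        for name, seq in zip(names, contigs):
            if name not in id_map:
                raise GenomeDBError(f"sequence {name!r} in {path} missing from id_map")
            gid = id_map[name]
            grouped.setdefault(gid, (name, []))[1].append(seq)
    return GenomeDB(
        [_make_record(gid, name, ctgs) for gid, (name, ctgs) in sorted(grouped.items())]
    )


def _read_fasta(path: str | os.PathLike) -> tuple[list[str], list[str]]:
    recs = list(SeqIO.parse(str(path), "fasta"))
    if not recs:
        raise GenomeDBError(f"FASTA file {path} is empty or not FASTA")
    return [str(r.seq).upper() for r in recs], [r.id for r in recs]


def load_genome_map(tsv_path: str | os.PathLike) -> GenomeDB:
    """Load a database described by a tab-separated genome map file with
    columns (fasta_path, genome_id, name); paths are resolved relative to
    the map file's directory."""
    base = Path(tsv_path).parent
    rows: list[tuple[Path, int, str]] = []
    with open(tsv_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise GenomeDBError(f"bad genome map row: {line!r}")
            rows.append((base / parts[0], int(parts[1]), parts[2]))
    ids = [gid for _, gid, _ in rows]
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        raise GenomeDBError(f"duplicate genome_id(s) in map: {sorted(dup)}")
    records = []
    for path, gid, name in rows:
        contigs, _ = _read_fasta(path)
        records.append(_make_record(gid, name, contigs))
    return GenomeDB(records)


def write_genomes(db: GenomeDB, directory: str | os.PathLike) -> list[Path]:
    """Write one FASTA file per genome; round-trips through load_genomes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in db:
        path = directory / f"genome_{rec.genome_id}.fasta"
        with open(path, "w") as fh:
            for k, c in enumerate(rec.contigs):
                header = rec.name if k == 0 else f"{rec.name}_contig{k}"
                fh.write(f">{header}\n")
                for i in range(0, len(c), 70):
                    fh.write(c[i : i + 70] + "\n")
        paths.append(path)
    return paths


def write_metadata(db: GenomeDB, path: str | os.PathLike) -> None:
    """Serialize database metadata as a versioned TSV."""
    with open(path, "w") as fh:
        fh.write(f"#genome_db_format\t{GENOME_DB_FORMAT_VERSION}\n")
        fh.write("genome_id\tname\tgenome_length\tn_contigs\n")
        for rec in db:
            fh.write(
                f"{rec.genome_id}\t{rec.name}\t{rec.genome_length}\t{len(rec.contigs)}\n"
            )
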