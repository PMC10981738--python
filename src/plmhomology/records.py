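"""Domain types and readers/writers for the formats the search pipeline touches.

Sequences travel as FASTA, domain annotations as PfamScan-style whitespace
tables, the family-to-clan lookup as a ``Pfam-A.clans.tsv``-dialect TSV, and
structural-similarity labels / SCOP-style fold labels as plain TSV tables.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino acids plus X (unknown).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"

_ACCESSION_RE = re.compile(r"^(PF\d+|CL\d+)(\.\d+)?$")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a dataset-unique identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"sequence for {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainAnnotation:
    """Pfam family hits for one protein; an empty set is legitimate."""

    protein_id: str
    family_ids: frozenset[str]

    def __post_init__(self) -> None:
        if any(not f for f in self.family_ids):
            raise ValueError(f"empty family accession for {self.protein_id!r}")


@dataclass(frozen=True)
class ClanMap:
    """Family accession -> clan accession lookup.

    Families absent from the map fall back to acting as their own clan
    (see :func:`plmhomology.clanfilter.assign_clans`).
    """

    family_to_clan: Mapping[str, str]

    def get(self, family: str) -> str | None:
        return self.family_to_clan.get(family)

    def __len__(self) -> int:
        return len(self.family_to_clan)

    def __contains__(self, family: str) -> bool:
        return family in self.family_to_clan


@dataclass(frozen=True)
class LabeledPair:
    """A query-target pair labeled with a structural similarity (TM-score)."""

    query_id: str
    target_id: str
    tm_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.tm_score <= 1.0:
            raise ValueError(
                f"tm_score {self.tm_score} for ({self.query_id},{self.target_id}) "
                "outside [0,1]"
            )


@dataclass(frozen=True)
class FoldLabel:
    """SCOP-style hierarchy labels: family ⊂ superfamily ⊂ fold."""

    protein_id: str
    family: str
    superfamily: str
    fold: str


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a FASTA file into :class:`ProteinRecord` objects, order preserved.

    The header token up to the first whitespace becomes the id. Sequences are
    upper-cased; letters outside the 20 amino acids plus X are kept but logged.
    Duplicate ids raise ``ValueError``.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate id {entry.id}")
        seen.add(entry.id)
        seq = str(entry.seq).upper()
        odd = sorted(set(seq) - set(ALPHABET))
        if odd:
            logger.warning(
                "sequence %s contains non-standard letters %s", entry.id, odd
            )
        records.append(ProteinRecord(entry.id, seq))
    if not records:
        logger.warning("FASTA file %s contains no records", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Clan map and domain annotations


def strip_version(accession: str) -> str:
    """Drop a trailing ``.NN`` version suffix from a Pfam accession."""
    return accession.split(".", 1)[0]


def read_clan_map(path: str | Path) -> ClanMap:
    """Read a family→clan TSV (``Pfam-A.clans.tsv`` dialect).

    Only the first two columns are used; rows whose clan field is empty are
    omitted (the unmapped-family fallback is applied downstream).
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 2 tab-separated columns, "
                    f"got {len(fields)}"
                )
            family, clan = fields[0].strip(), fields[1].strip()
            if not family:
                raise ValueError(f"{path}:{lineno}: empty family accession")
            if clan:
                mapping[strip_version(family)] = clan
    return ClanMap(mapping)


def read_domain_annotations(path: str | Path) -> list[DomainAnnotation]:
    """Parse PfamScan-style tabular output into per-protein annotations.

    The table is whitespace-delimited; lines starting with ``#`` are comments.
    The first column is the sequence id and the hmm accession is located as
    the first ``PF``/``CL`` token on the row (PfamScan puts it in column 6,
    but two-column tables are accepted too). Version suffixes are stripped.
    """
    hits: dict[str, set[str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            protein_id = fields[0]
            accession = next(
                (f for f in fields[1:] if _ACCESSION_RE.match(f)), None
            )
            if accession is None:
                raise ValueError(
                    f"{path}:{lineno}: missing hmm accession column"
                )
            if protein_id not in hits:
                hits[protein_id] = set()
                order.append(protein_id)
            hits[protein_id].add(strip_version(accession))
    return [DomainAnnotation(pid, frozenset(hits[pid])) for pid in order]


def write_domain_annotations(
    annotations: Iterable[DomainAnnotation], path: str | Path
) -> None:
    """Write annotations as a minimal two-column PfamScan-style table."""
    with open(path, "w") as fh:
        fh.write("# <seq id> <hmm acc>\n")
        for ann in annotations:
            for fam in sorted(ann.family_ids):
                fh.write(f"{ann.protein_id} {fam}\n")


def write_clan_map(clan_map: ClanMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for family in sorted(clan_map.family_to_clan):
            fh.write(f"{family}\t{clan_map.family_to_clan[family]}\n")


# ---------------------------------------------------------------------------
# Label tables


def read_labeled_pairs(path: str | Path) -> list[LabeledPair]:
    """Read a TSV of (query_id, target_id, tm_score) training labels."""
    pairs: list[LabeledPair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                )
            try:
                tm = float(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad tm_score") from exc
            pairs.append(LabeledPair(fields[0], fields[1], tm))
    return pairs


def write_labeled_pairs(pairs: Iterable[LabeledPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.query_id}\t{p.target_id}\t{p.tm_score:.6f}\n")


def read_fold_labels(path: str | Path) -> dict[str, FoldLabel]:
    """Read a TSV of (protein_id, family, superfamily, fold) labels.

    The hierarchy is validated on load: a family must map to a single
    superfamily and a superfamily to a single fold across the whole table.
    """
    labels: dict[str, FoldLabel] = {}
    fam_to_sf: dict[str, str] = {}
    sf_to_fold: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 columns, got {len(fields)}"
                )
            pid, fam, sf, fold = fields[:4]
            label = FoldLabel(pid, fam, sf, fold)
            validate_fold_hierarchy([label], fam_to_sf, sf_to_fold)
            labels[pid] = label
    return labels


def validate_fold_hierarchy(
    labels: Iterable[FoldLabel],
    _fam_to_sf: dict[str, str] | None = None,
    _sf_to_fold: dict[str, str] | None = None,
) -> None:
    """Raise ``ValueError`` if family→superfamily→fold is not a function."""
    fam_to_sf = {} if _fam_to_sf is None else _fam_to_sf
    sf_to_fold = {} if _sf_to_fold is None else _sf_to_fold
    for lab in labels:
        prev_sf = fam_to_sf.setdefault(lab.family, lab.superfamily)
        if prev_sf != lab.superfamily:
            raise ValueError(
                f"family {lab.family} maps to superfamilies "
                f"{prev_sf} and {lab.superfamily}"
            )
        prev_fold = sf_to_fold.setdefault(lab.superfamily, lab.fold)
        if prev_fold != lab.fold:
            raise ValueError(
                f"superfamily {lab.superfamily} maps to folds "
                f"{prev_fold} and {lab.fold}"
            )


def write_fold_labels(
    labels: Mapping[str, FoldLabel] | Iterable[FoldLabel], path: str | Path
) -> None:
    if isinstance(labels, Mapping):
        labels = labels.values()
    with open(path, "w") as fh:
        for lab in labels:
            fh.write(f"{lab.protein_id}\t{lab.family}\t{lab.superfamily}\t{lab.fold}\n")
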