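"""Reading and writing of sequences, interaction labels and residue similarity measures.

Datasets for ligand-specificity classification consist of three pieces:

* a multi-FASTA file of amino acid sequences (one record per protein),
* a table of protein-ligand interaction labels, either *wide* (a binary
  protein x ligand matrix) or *long* (a list of positive pairs; every pair
  not listed is a conditionally negative example), and
* a residue similarity measure -- plain identity by default, or any
  substitution matrix in NCBI text format (e.g. BLOSUM62).

Ligand classes with fewer than ``min_class_size`` member proteins are
dropped at load time: small classes do not support reliable classification.
Proteins left without any class are kept as complement-only examples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("posim")

#: the 20 standard one-letter codes plus common ambiguity/rare codes
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_RESIDUES = "XBZUO"
ALLOWED_RESIDUES = frozenset(STANDARD_RESIDUES + AMBIGUOUS_RESIDUES)


class DataError(ValueError):
    """Raised when an input file violates a dataset invariant."""


@dataclass(frozen=True)
class SequenceRecord:
    """An identified amino acid sequence.

    Parameters
    ----------
    id : str
        Unique accession; for FASTA input this is the header token before
        the first whitespace (UniProt-style).
    residues : str
        Uppercase amino acid string over the 20 standard codes plus
        ambiguity codes (X, B, Z, U, O).
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise DataError("sequence record requires a non-empty id")
        if not self.residues:
            raise DataError(f"sequence {self.id!r} is empty")
        res = self.residues.upper()
        bad = set(res) - ALLOWED_RESIDUES
        if bad:
            raise DataError(
                f"sequence {self.id!r} contains invalid residues: {sorted(bad)}"
            )
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class InteractionTable:
    """Binary protein x ligand-class membership.

    ``member[i, j] == 1`` means protein ``protein_ids[i]`` interacts with
    ligand ``ligand_ids[j]``.  For a given ligand class C the member
    proteins carry class weight a_k(C) = 1 and every other protein belongs
    to the complement, b_k(C) = 1 - a_k(C).
    """

    protein_ids: list[str]
    ligand_ids: list[str]
    member: np.ndarray
    dropped_ligands: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.member = np.asarray(self.member, dtype=np.int8)
        if self.member.shape != (len(self.protein_ids), len(self.ligand_ids)):
            raise DataError(
                f"membership matrix shape {self.member.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.ligand_ids)} ligands"
            )
        if not np.isin(self.member, (0, 1)).all():
            raise DataError("membership matrix cells must be 0 or 1")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise DataError("duplicate protein ids in interaction table")
        if len(set(self.ligand_ids)) != len(self.ligand_ids):
            raise DataError("duplicate ligand ids in interaction table")
        self._protein_index = {p: i for i, p in enumerate(self.protein_ids)}
        self._ligand_index = {l: j for j, l in enumerate(self.ligand_ids)}

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_ligands(self) -> int:
        return len(self.ligand_ids)

    def class_weights(self, ligand_id: str) -> np.ndarray:
        """Binary class weights a_k(C) for ligand class C, in protein order."""
        return self.member[:, self._ligand_index[ligand_id]].astype(np.int8)

    def membership(self, protein_id: str, ligand_id: str) -> int:
        return int(
            self.member[self._protein_index[protein_id], self._ligand_index[ligand_id]]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.member, index=self.protein_ids, columns=self.ligand_ids
        )

    def drop_protein(self, protein_id: str) -> "InteractionTable":
        """Return a copy with one protein's row removed (used by LOOCV)."""
        i = self._protein_index[protein_id]
        keep = [p for p in self.protein_ids if p != protein_id]
        return InteractionTable(
            keep, list(self.ligand_ids), np.delete(self.member, i, axis=0)
        )

    def filtered(self, min_class_size: int) -> "InteractionTable":
        """Drop ligand classes with fewer than ``min_class_size`` members.

        Proteins left with no class stay in the table as complement-only
        examples.  Idempotent: filtering a filtered table is a no-op.
        """
        sizes = self.member.sum(axis=0)
        keep = sizes >= min_class_size
        dropped = [l for l, k in zip(self.ligand_ids, keep) if not k]
        for lig in dropped:
            logger.warning(
                "dropping ligand class %r: %d member(s) < min_class_size %d",
                lig,
                int(sizes[self.ligand_ids.index(lig)]),
                min_class_size,
            )
        kept_ligands = [l for l, k in zip(self.ligand_ids, keep) if k]
        if not kept_ligands:
            raise DataError(
                f"no ligand class has min_class_size={min_class_size} or more "
                "member proteins; empty table after filtering"
            )
        return InteractionTable(
            list(self.protein_ids),
            kept_ligands,
            self.member[:, keep],
            dropped_ligands=list(self.dropped_ligands) + dropped,
        )


@dataclass(frozen=True)
class ResidueSimilarity:
    """A symmetric residue-pair score lookup.

    ``kind="identity"`` scores 1 for equal standard residues and 0
    otherwise; ambiguity codes (X, B, Z, U, O) score 0 against everything,
    including themselves, because an uncertain residue carries no match
    evidence.  ``kind="matrix"`` uses substitution-matrix values verbatim.
    """

    kind: str
    name: str = "identity"
    _matrix: "substitution_matrices.Array | None" = None

    def __call__(self, a: str, b: str) -> float:
        if self.kind == "identity":
            if a == b and a in STANDARD_RESIDUES:
                return 1.0
            return 0.0
        try:
            return float(self._matrix[a, b])  # type: ignore[index]
        except (KeyError, IndexError) as exc:
            raise DataError(
                f"substitution matrix {self.name!r} has no entry for pair "
                f"({a!r}, {b!r})"
            ) from exc

    def pair_matrix(self, q: str, k: str) -> np.ndarray:
        """Dense len(q) x len(k) similarity matrix for two sequences."""
        qa = np.frombuffer(q.encode("ascii"), dtype=np.uint8)
        ka = np.frombuffer(k.encode("ascii"), dtype=np.uint8)
        if self.kind == "identity":
            standard = np.frombuffer(STANDARD_RESIDUES.encode("ascii"), dtype=np.uint8)
            q_ok = np.isin(qa, standard)
            return (
                (qa[:, None] == ka[None, :]) & q_ok[:, None]
            ).astype(np.float64)
        lut = np.zeros((128, 128))
        residues = sorted(set(q) | set(k))
        for a in residues:
            for b in residues:
                lut[ord(a), ord(b)] = self(a, b)
        return lut[qa[:, None], ka[None, :]]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-FASTA file of amino acid sequences.

    Record order is preserved, residues are uppercased, and the id is the
    header token before the first whitespace.  Duplicate ids and empty
    sequences are hard errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DataError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise DataError(f"empty sequence for id {rec.id!r} in {path}")
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise DataError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as unwrapped multi-FASTA."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta-2line")


def read_interactions(
    path: str | Path,
    dialect: str = "wide",
    min_class_size: int = 5,
) -> InteractionTable:
    """Read protein-ligand interaction labels from a TSV file.

    ``dialect="wide"``: header row of ligand ids, one row per protein with
    0/1 cells.  ``dialect="long"``: two columns ``protein_id<TAB>ligand_id``
    listing positive pairs only; any pair not listed is a conditionally
    negative example and becomes a 0 cell.

    Ligand classes with fewer than ``min_class_size`` members are dropped
    (and logged); an empty table after filtering is an error.
    """
    path = Path(path)
    if dialect == "wide":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        cells = df.to_numpy()
        bad = ~np.isin(cells, ("0", "1"))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataError(
                f"wide interaction table cell ({df.index[i]!r}, {df.columns[j]!r}) "
                f"is {cells[i, j]!r}; cells must be 0 or 1"
            )
        table = InteractionTable(
            [str(p) for p in df.index],
            [str(l) for l in df.columns],
            cells.astype(np.int8),
        )
    elif dialect == "long":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["protein_id", "ligand_id"], dtype=str
        )
        proteins = list(dict.fromkeys(df["protein_id"]))
        ligands = list(dict.fromkeys(df["ligand_id"]))
        member = np.zeros((len(proteins), len(ligands)), dtype=np.int8)
        p_idx = {p: i for i, p in enumerate(proteins)}
        l_idx = {l: j for j, l in enumerate(ligands)}
        for p, l in zip(df["protein_id"], df["ligand_id"]):
            member[p_idx[p], l_idx[l]] = 1
        table = InteractionTable(proteins, ligands, member)
    else:
        raise DataError(f"unknown interaction dialect {dialect!r}; use 'wide' or 'long'")
    return table.filtered(min_class_size)


def write_interactions(
    table: InteractionTable, path: str | Path, dialect: str = "wide"
) -> None:
    path = Path(path)
    if dialect == "wide":
        table.to_frame().to_csv(path, sep="\t")
    elif dialect == "long":
        rows = [
            (p, l)
            for i, p in enumerate(table.protein_ids)
            for j, l in enumerate(table.ligand_ids)
            if table.member[i, j]
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
    else:
        raise DataError(f"unknown interaction dialect {dialect!r}")


def check_ids(
    sequences: Sequence[SequenceRecord], table: InteractionTable
) -> None:
    """Verify that every protein in the table has a sequence."""
    have = {r.id for r in sequences}
    missing = [p for p in table.protein_ids if p not in have]
    if missing:
        raise DataError(
            f"interaction table references protein id(s) with no sequence: "
            f"{missing[:5]}"
        )


def load_similarity(spec: str | Path = "identity") -> ResidueSimilarity:
    """Load a residue similarity measure.

    ``"identity"`` gives the default exact-match measure.  Any other value
    is read as a substitution matrix file in NCBI text layout ('#' comment
    lines, a header row of residues, one labelled row per residue); the
    matrix must be symmetric and square.
    """
    if str(spec).lower() == "identity":
        return ResidueSimilarity(kind="identity", name="identity")
    path = Path(spec)
    if not path.exists():
        raise DataError(f"substitution matrix file not found: {path}")
    try:
        mat = substitution_matrices.read(str(path))
    except Exception as exc:
        raise DataError(f"cannot parse substitution matrix {path}: {exc}") from exc
    arr = np.asarray(mat)
    if arr.shape[0] != arr.shape[1] or mat.alphabet is None:
        raise DataError(f"substitution matrix {path} is not square")
    if not np.allclose(arr, arr.T):
        raise DataError(f"substitution matrix {path} is not symmetric")
    return ResidueSimilarity(kind="matrix", name=path.name, _matrix=mat)
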