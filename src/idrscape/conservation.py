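"""Reference-anchored MSA parsing and per-position conservation scoring.

The conservation score of reference position i is

    CS_i = n_i(match) / N_i(non-gap)

where n_i counts homologs whose residue at column i equals the reference
residue and N_i counts homologs with any non-gap residue there.  The
reference itself is excluded from both counts: the score measures occurrence
of the reference letter *in homologs*.  Homologs below a percent-identity
floor (default 20%, computed as matches over the full aligned length
including gap columns) are discarded before scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO

from .exceptions import FormatError, ShapeError

GAP = "-"


@dataclass
class AlignmentSet:
    """An MSA anchored on a designated reference sequence.

    All aligned strings have equal length; columns map 1:1 to reference
    alignment coordinates (A3M insertion columns are removed at parse time).
    """

    reference_id: str
    reference_aligned: str
    homologs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        L = len(self.reference_aligned)
        for hid, s in self.homologs:
            if len(s) != L:
                raise FormatError(
                    f"homolog {hid}: aligned length {len(s)} != reference {L}"
                )
        if set(self.reference_aligned) <= {GAP}:
            raise FormatError("reference alignment row contains no residues")

    def __len__(self) -> int:
        return len(self.homologs)


def _strip_a3m_insertions(seq: str) -> str:
    # lowercase letters are insertions relative to the reference profile;
    # '.' (their placeholder in other rows) is read as a gap
    return "".join(GAP if c == "." else c for c in seq if not c.islower())


def _read_fasta_like(path) -> list[tuple[str, str]]:
    records: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                records.append((line[1:].split()[0], []))
            elif line.startswith("#"):
                continue
            else:
                if not records:
                    raise FormatError(f"{path}: sequence data before first header")
                records[-1][1].append(line)
    return [(name, "".join(chunks)) for name, chunks in records]


def parse_alignment(path, format: str | None = None,
                    reference_id: str | None = None) -> AlignmentSet:
    """Parse an MSA file into an :class:`AlignmentSet`.

    Parameters
    ----------
    path : file path
    format : one of {"a3m", "clustal", "aligned-fasta"}; inferred from the
        extension when omitted (.a3m / .aln|.clustal|.clw / .fasta|.afa|.fa).
    reference_id : sequence designated as the reference; defaults to the
        first sequence in the file.
    """
    path = Path(path)
    if format is None:
        ext = path.suffix.lower()
        format = {".a3m": "a3m", ".aln": "clustal", ".clustal": "clustal",
                  ".clw": "clustal", ".fasta": "aligned-fasta",
                  ".afa": "aligned-fasta", ".fa": "aligned-fasta"}.get(ext)
        if format is None:
            raise FormatError(f"cannot infer alignment format from {path.name!r}")

    if format == "a3m":
        raw = _read_fasta_like(path)
        rows = [(name, _strip_a3m_insertions(seq)) for name, seq in raw]
    elif format == "clustal":
        try:
            aln = AlignIO.read(str(path), "clustal")
        except ValueError as e:
            raise FormatError(f"{path}: {e}") from e
        rows = [(rec.id, str(rec.seq).replace(".", GAP)) for rec in aln]
    elif format == "aligned-fasta":
        raw = _read_fasta_like(path)
        rows = [(name, seq.replace(".", GAP)) for name, seq in raw]
    else:
        raise FormatError(f"unknown alignment format {format!r}")

    if not rows:
        raise FormatError(f"{path}: empty alignment")
    lengths = {len(s) for _, s in rows}
    if len(lengths) != 1:
        raise FormatError(
            f"{path}: ragged alignment, row lengths {sorted(lengths)}"
        )

    rows = [(name, seq.upper()) for name, seq in rows]
    if reference_id is None:
        ref_name, ref_seq = rows[0]
        homologs = rows[1:]
    else:
        matches = [r for r in rows if r[0] == reference_id]
        if not matches:
            raise FormatError(f"{path}: reference {reference_id!r} not found")
        ref_name, ref_seq = matches[0]
        homologs = [r for r in rows if r[0] != reference_id]
    return AlignmentSet(ref_name, ref_seq, homologs)


def percent_identity(homolog_aligned: str, reference_aligned: str) -> float:
    """Fraction of aligned columns where homolog and reference letters match.

    The numerator requires both letters non-gap (case-insensitive); the
    denominator is the full aligned length, gap columns included.
    """
    if len(homolog_aligned) != len(reference_aligned):
        raise ShapeError(
            f"aligned lengths differ: {len(homolog_aligned)} vs {len(reference_aligned)}"
        )
    N = len(reference_aligned)
    if N == 0:
        raise ShapeError("empty alignment strings")
    n = sum(
        1
        for h, r in zip(homolog_aligned.upper(), reference_aligned.upper())
        if h == r and h != GAP and r != GAP
    )
    return n / N


def filter_homologs(a: AlignmentSet, min_identity: float = 0.20) -> AlignmentSet:
    """Retain homologs with percent identity ≥ min_identity (inclusive)."""
    kept = [
        (hid, seq)
        for hid, seq in a.homologs
        if percent_identity(seq, a.reference_aligned) >= min_identity
    ]
    return AlignmentSet(a.reference_id, a.reference_aligned, kept)


def conservation_scores(a: AlignmentSet) -> pd.DataFrame:
    """Per-residue conservation track over the reference's non-gap columns.

    Returns a DataFrame with columns protein_id, position (1-based over
    reference residues), wt_aa, cs, n_match, n_nongap.  Columns where the
    reference has a gap carry no reference residue and are dropped; columns
    where every homolog has a gap yield a missing (NaN) score — absence of
    evidence, not evidence of divergence.
    """
    ref = a.reference_aligned.upper()
    cols = [i for i, c in enumerate(ref) if c != GAP]
    if not a.homologs:
        warnings.warn(
            f"{a.reference_id}: no homologs after filtering; "
            "all conservation scores missing",
            stacklevel=2,
        )
    hom_arr = (
        np.array([list(seq.upper()) for _, seq in a.homologs])
        if a.homologs
        else np.empty((0, len(ref)), dtype="<U1")
    )
    records = []
    for pos, i in enumerate(cols, start=1):
        col = hom_arr[:, i] if hom_arr.size else np.array([], dtype="<U1")
        nongap = col != GAP
        n_nongap = int(nongap.sum())
        n_match = int((col[nongap] == ref[i]).sum())
        cs = n_match / n_nongap if n_nongap > 0 else np.nan
        records.append((a.reference_id, pos, ref[i], cs, n_match, n_nongap))
    return pd.DataFrame(
        records,
        columns=["protein_id", "position", "wt_aa", "cs", "n_match", "n_nongap"],
    )


def write_conservation(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", index=False, float_format="%.10g")
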