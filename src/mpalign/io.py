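"""Readers and writers for every on-disk format the toolkit touches.

All coordinates in on-disk artifacts are 1-based and inclusive.  Formats:

* FASTA (unaligned input), via Biopython.
* Aligned FASTA: exactly two records of equal length with ``-`` or ``.``
  gaps; aligned pairs are the columns where both records are non-gap.
* Pairs TSV: header ``i<TAB>j`` then one 1-based index pair per row.
* Score-matrix TSV: tab-separated with 1-based position headers.
* Pair-HMM parameter file: ``key value`` lines (``topology``, ``delta``,
  ``epsilon``, ``tau``, optional ``emission_table`` path).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .message_passing import ScoreMatrix
from .pairhmm import PairHMMParams
from .seqtypes import BioSequence, PairwiseAlignment
from .substitution import build_default_joint_model, read_joint_table

GAP_CHARS = "-."


def read_fasta(path, alphabet_kind: str = "protein") -> list[BioSequence]:
    """Read FASTA records in order; rejects empty files, duplicate ids and
    illegal residues (with the offending symbol and position)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append(BioSequence(rec.id, str(rec.seq), alphabet_kind))
    return out


def write_fasta(seqs: list[BioSequence], path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reference_pair(
    path, alphabet_kind: str = "protein"
) -> tuple[BioSequence, BioSequence, PairwiseAlignment]:
    """Read a two-record aligned FASTA; returns the ungapped sequences and
    the alignment of all columns where both records are non-gap."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(
            f"expected exactly 2 aligned records in {path}, found {len(records)}"
        )
    a, b = (str(r.seq) for r in records)
    if len(a) != len(b):
        raise ValueError(
            f"aligned records differ in length ({len(a)} vs {len(b)}) in {path}"
        )
    pairs = []
    i = j = 0
    for ca, cb in zip(a, b):
        ga, gb = ca in GAP_CHARS, cb in GAP_CHARS
        if not ga:
            i += 1
        if not gb:
            j += 1
        if not ga and not gb:
            pairs.append((i, j))
    x = BioSequence(records[0].id, a.replace("-", "").replace(".", ""), alphabet_kind)
    y = BioSequence(records[1].id, b.replace("-", "").replace(".", ""), alphabet_kind)
    return x, y, PairwiseAlignment(pairs, (len(x), len(y)))


def render_aligned(
    x: BioSequence, y: BioSequence, aln: PairwiseAlignment
) -> tuple[str, str]:
    """Column rendering of a pair set: between anchor pairs, unaligned
    residues of x are emitted (over gaps) before those of y."""
    if aln.lengths != (len(x), len(y)):
        raise ValueError("alignment lengths do not match the sequences")
    rows_x, rows_y = [], []
    pi, pj = 0, 0
    for i, j in list(aln.pairs) + [(len(x) + 1, len(y) + 1)]:
        for k in range(pi + 1, i):
            rows_x.append(x[k])
            rows_y.append("-")
        for k in range(pj + 1, j):
            rows_x.append("-")
            rows_y.append(y[k])
        if i <= len(x) and j <= len(y):
            rows_x.append(x[i])
            rows_y.append(y[j])
        pi, pj = i, j
    return "".join(rows_x), "".join(rows_y)


def write_pairwise_alignment(
    x: BioSequence,
    y: BioSequence,
    aln: PairwiseAlignment,
    path,
    format: str = "aligned_fasta",
) -> None:
    """Write an alignment as aligned FASTA or as a pairs TSV."""
    if format == "aligned_fasta":
        ax, ay = render_aligned(x, y, aln)
        records = [
            SeqRecord(Seq(ax), id=x.id, description=""),
            SeqRecord(Seq(ay), id=y.id, description=""),
        ]
        SeqIO.write(records, str(path), "fasta")
    elif format == "pairs_tsv":
        write_pairs_tsv(aln, path)
    else:
        raise ValueError(f"unknown alignment format {format!r}")


def write_pairs_tsv(aln: PairwiseAlignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("i\tj\n")
        for i, j in aln.pairs:
            fh.write(f"{i}\t{j}\n")


def read_pairs_tsv(path, lengths: tuple[int, int]) -> PairwiseAlignment:
    pairs = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("i\t"):
            continue
        try:
            i, j = map(int, line.split("\t"))
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: malformed pair row {line!r}") from exc
        pairs.append((i, j))
    return PairwiseAlignment(pairs, lengths)


def write_score_matrix_tsv(S: ScoreMatrix, path) -> None:
    """Tab-separated matrix with 1-based x positions as rows and y positions
    as columns; 17 significant digits (lossless float64 round-trip)."""
    L, M = S.shape
    with open(path, "w") as fh:
        fh.write("pos\t" + "\t".join(str(j) for j in range(1, M + 1)) + "\n")
        for i in range(L):
            fh.write(
                str(i + 1)
                + "\t"
                + "\t".join(f"{v:.17g}" for v in S.values[i])
                + "\n"
            )


def read_score_matrix_tsv(path) -> ScoreMatrix:
    lines = Path(path).read_text().splitlines()
    rows = [
        [float(v) for v in ln.split("\t")[1:]]
        for ln in lines[1:]
        if ln.strip()
    ]
    return ScoreMatrix(np.array(rows))


def write_params_file(params: PairHMMParams, path, emission_table=None) -> None:
    """Write a gap-parameter file.  Only models built from (delta, epsilon,
    tau) gap parameters round-trip exactly through this format."""
    delta = float(params.transitions[0, 1])
    epsilon = float(params.transitions[1, 1])
    tau = float(params.terminate[0])
    with open(path, "w") as fh:
        fh.write(f"topology {params.topology}\n")
        fh.write(f"delta {delta:.17g}\n")
        fh.write(f"epsilon {epsilon:.17g}\n")
        fh.write(f"tau {tau:.17g}\n")
        if emission_table is not None:
            fh.write(f"emission_table {emission_table}\n")


def read_params_file(path, alphabet_kind: str = "protein") -> PairHMMParams:
    """Read a ``key value`` parameter file (keys: topology, delta, epsilon,
    tau, emission_table); missing keys take the package defaults."""
    kv: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: malformed parameter line {line!r}")
        kv[parts[0]] = parts[1]
    known = {"topology", "delta", "epsilon", "tau", "emission_table"}
    unknown = set(kv) - known
    if unknown:
        raise ValueError(f"{path}: unknown parameter keys {sorted(unknown)}")
    if "emission_table" in kv:
        table_path = Path(kv["emission_table"])
        if not table_path.is_absolute():
            table_path = Path(path).parent / table_path
        model = read_joint_table(table_path, alphabet_kind)
    else:
        model = build_default_joint_model(alphabet_kind)
    from .pairhmm import DEFAULT_DELTA, DEFAULT_EPSILON, DEFAULT_TAU

    return PairHMMParams.from_gap_params(
        delta=float(kv.get("delta", DEFAULT_DELTA)),
        epsilon=float(kv.get("epsilon", DEFAULT_EPSILON)),
        tau=float(kv.get("tau", DEFAULT_TAU)),
        topology=kv.get("topology", "full"),
        match_emission=model,
    )
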