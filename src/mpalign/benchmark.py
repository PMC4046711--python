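"""Synthetic pair-HMM benchmark sets with known true alignments.

Homologous pairs are sampled from the generative pair-HMM, so every pair
carries its exact column-wise truth (the M-state columns of the generating
path).  Divergence is controlled by a single knob t in [0, 1] that
geometrically flattens the joint match emission toward the product of its
marginals::

    P_t(a, b)  proportional to  P(a, b)^(1-t) * (p(a) p(b))^t

t = 0 reproduces the base model (homolog-like pairs); t = 1 makes aligned
columns statistically independent (random-like pairs), so the expected
percent identity of true columns decreases monotonically in t.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .pairhmm import PairHMMParams, SimulatedPair, sample_pair
from .seqtypes import BioSequence, PairwiseAlignment
from .substitution import JointSubstitutionModel
from . import io as mio

MANIFEST_NAME = "manifest.json"


@dataclass(frozen=True)
class BenchmarkEntry:
    pair_id: str
    fasta: str
    truth: str
    seed: int


@dataclass(frozen=True)
class BenchmarkManifest:
    entries: tuple[BenchmarkEntry, ...]
    global_seed: int
    divergence_knob: float
    gap_params: dict
    root: Path


def flatten_model(
    model: JointSubstitutionModel, t: float
) -> JointSubstitutionModel:
    """Geometrically interpolate the joint table toward independence."""
    if not 0.0 <= t <= 1.0:
        raise ValueError("divergence knob must be in [0, 1]")
    p = model.marginal
    J = model.joint ** (1.0 - t) * np.outer(p, p) ** t
    J = (J + J.T) / 2.0  # exact symmetry under floating point
    J /= J.sum()
    return JointSubstitutionModel(
        model.alphabet, J, J.sum(axis=1), model.alphabet_kind
    )


def percent_identity(pair: SimulatedPair) -> float:
    """Fraction of true aligned columns with identical residues (0 if the
    truth is empty)."""
    if not pair.truth.pairs:
        return 0.0
    same = sum(1 for i, j in pair.truth.pairs if pair.x[i] == pair.y[j])
    return same / len(pair.truth.pairs)


def entry_seeds(global_seed: int, n: int) -> np.ndarray:
    """Distinct per-entry seeds, deterministically derived from global_seed."""
    rng = np.random.default_rng(global_seed)
    seeds: list[int] = []
    seen: set[int] = set()
    while len(seeds) < n:
        s = int(rng.integers(1, 2**31 - 1))
        if s not in seen:
            seen.add(s)
            seeds.append(s)
    return np.array(seeds, dtype=np.int64)


def sample_benchmark_pairs(
    params: PairHMMParams,
    n_pairs: int,
    divergence_knob: float,
    min_len: int,
    global_seed: int,
) -> list[SimulatedPair]:
    """Sample ``n_pairs`` pairs from the divergence-flattened model (no I/O)."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    gen_model = flatten_model(params.match_emission, divergence_knob)
    gen_params = PairHMMParams(
        topology=params.topology,
        transitions=params.transitions,
        start_dist=params.start_dist,
        terminate=params.terminate,
        match_emission=gen_model,
        insert_emission=params.insert_emission,
    )
    return [
        sample_pair(gen_params, int(s), min_len)
        for s in entry_seeds(global_seed, n_pairs)
    ]


def generate_benchmark(
    params: PairHMMParams,
    n_pairs: int,
    divergence_knob: float,
    min_len: int,
    global_seed: int,
    out_dir,
) -> BenchmarkManifest:
    """Write ``n_pairs`` FASTA files, truth TSVs and a JSON manifest.

    Fully reproducible from ``global_seed``; per-entry seeds are distinct
    and derived from it.
    """
    root = Path(out_dir)
    try:
        root.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create benchmark directory {root}: {exc}") from exc
    pairs = sample_benchmark_pairs(
        params, n_pairs, divergence_knob, min_len, global_seed
    )
    width = max(3, len(str(n_pairs - 1)))
    entries = []
    for k, sp in enumerate(pairs):
        pair_id = f"pair_{k:0{width}d}"
        fasta = f"{pair_id}.fasta"
        truth = f"{pair_id}.truth.tsv"
        mio.write_fasta(
            [
                BioSequence(f"{pair_id}_x", sp.x.residues, sp.x.alphabet_kind),
                BioSequence(f"{pair_id}_y", sp.y.residues, sp.y.alphabet_kind),
            ],
            root / fasta,
        )
        mio.write_pairs_tsv(sp.truth, root / truth)
        entries.append(
            BenchmarkEntry(pair_id=pair_id, fasta=fasta, truth=truth, seed=sp.seed)
        )
    gap_params = {
        "topology": params.topology,
        "delta": float(params.transitions[0, 1]),
        "epsilon": float(params.transitions[1, 1]),
        "tau": float(params.terminate[0]),
        "min_len": int(min_len),
    }
    manifest = BenchmarkManifest(
        entries=tuple(entries),
        global_seed=int(global_seed),
        divergence_knob=float(divergence_knob),
        gap_params=gap_params,
        root=root,
    )
    payload = {
        "global_seed": manifest.global_seed,
        "divergence_knob": manifest.divergence_knob,
        "gap_params": gap_params,
        "entries": [
            {"pair_id": e.pair_id, "fasta": e.fasta, "truth": e.truth, "seed": e.seed}
            for e in entries
        ],
    }
    (root / MANIFEST_NAME).write_text(json.dumps(payload, indent=1) + "\n")
    return manifest


def load_manifest(path) -> BenchmarkManifest:
    """Load a manifest written by :func:`generate_benchmark`; ``path`` may be
    the manifest file or its directory."""
    p = Path(path)
    if p.is_dir():
        p = p / MANIFEST_NAME
    payload = json.loads(p.read_text())
    entries = tuple(
        BenchmarkEntry(
            pair_id=e["pair_id"], fasta=e["fasta"], truth=e["truth"], seed=e["seed"]
        )
        for e in payload["entries"]
    )
    return BenchmarkManifest(
        entries=entries,
        global_seed=payload["global_seed"],
        divergence_knob=payload["divergence_knob"],
        gap_params=payload["gap_params"],
        root=p.parent,
    )


def load_entry(
    manifest: BenchmarkManifest, entry: BenchmarkEntry, alphabet_kind="protein"
) -> tuple[BioSequence, BioSequence, PairwiseAlignment]:
    seqs = mio.read_fasta(manifest.root / entry.fasta, alphabet_kind)
    if len(seqs) != 2:
        raise ValueError(f"{entry.fasta}: expected 2 records, found {len(seqs)}")
    x, y = seqs
    truth = mio.read_pairs_tsv(
        manifest.root / entry.truth, (len(x), len(y))
    )
    return x, y, truth
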