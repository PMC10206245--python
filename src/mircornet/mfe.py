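"""miRNA:mRNA duplex minimum free energy (intermolecular-only, RNAhybrid-like).

The hybridization model considers only intermolecular base pairs (no
intramolecular structure in either strand). Watson-Crick and G:U pairs are
allowed; consecutive pairs are scored with the embedded Turner 2004
nearest-neighbor stack table; bulge and internal loops (up to 15 unpaired
nucleotides) carry a tabulated length-dependent initiation penalty plus an
asymmetry term; a duplex initiation penalty is applied once. The minimum
free energy (mfe) is the best total over every target start position; 0 is
returned when no stable (negative-energy) duplex exists.

Per-gene affinity is the arithmetic mean of the per-transcript mfe, and a
gene passes the affinity filter when that average is strictly below
-20 kcal/mol (the conventional miRNA-target affinity cutoff).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from numba import njit

from mircornet.targets import _normalize

MFE_CUTOFF = -20.0
MAX_LOOP = 15

_NT = {"A": 0, "C": 1, "G": 2, "U": 3}
_PAIR_NAMES = ("CG", "GC", "GU", "UG", "AU", "UA")
#: (top, bottom) nucleotide indices -> pair type 0..5, -1 = not pairable
_PAIR_TYPE = -np.ones((4, 4), dtype=np.int64)
for _k, (_a, _b) in enumerate(_PAIR_NAMES):
    _PAIR_TYPE[_NT[_a], _NT[_b]] = _k


@dataclass(frozen=True)
class DuplexParams:
    stack: np.ndarray  # 6x6, indexed [type(pair1), type(reversed pair2)]
    bulge: np.ndarray  # initiation by loop length, index 0 unused
    internal: np.ndarray
    ninio_per_nt: float
    ninio_max: float
    init: float


@lru_cache(maxsize=1)
def load_params() -> DuplexParams:
    """Parse the embedded energy file and assert table symmetry.

    The stack table must be symmetric (reading a stack from the opposite
    strand gives the same energy); this nearest-neighbor identity is
    asserted at load.
    """
    stack = np.full((6, 6), np.nan)
    bulge = np.full(MAX_LOOP + 1, np.inf)
    internal = np.full(MAX_LOOP + 1, np.inf)
    ninio = (0.0, 0.0)
    init = 0.0
    text = (
        importlib.resources.files("mircornet")
        .joinpath("data/duplex_energies.txt")
        .read_text()
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] == "stack":
            i, j = _PAIR_NAMES.index(parts[1]), _PAIR_NAMES.index(parts[2])
            stack[i, j] = float(parts[3])
        elif parts[0] == "bulge":
            bulge[int(parts[1])] = float(parts[2])
        elif parts[0] == "internal":
            internal[int(parts[1])] = float(parts[2])
        elif parts[0] == "ninio":
            ninio = (float(parts[1]), float(parts[2]))
        elif parts[0] == "init":
            init = float(parts[1])
    if np.isnan(stack).any():
        raise ValueError("incomplete stack table")
    if not np.array_equal(stack, stack.T):
        raise ValueError("stack table violates nearest-neighbor symmetry")
    return DuplexParams(stack, bulge, internal, ninio[0], ninio[1], init)


def stack_energy(pair1: str, pair2: str) -> float:
    """Stack energy of pair2 following pair1 (pairs as top+bottom symbols).

    ``stack_energy("GC", "CG")`` is the energy of 5'-GC-3' over 3'-CG-5'.
    """
    p = load_params()
    t1 = _PAIR_NAMES.index(pair1)
    t2 = _PAIR_NAMES.index(pair2[::-1])
    return float(p.stack[t1, t2])


@njit(cache=True)
def _duplex_core(
    mir, tgt, stack, bulge, internal, ninio_per_nt, ninio_max, init, pair_type
):  # pragma: no cover - exercised via duplex_mfe()
    m, t = mir.shape[0], tgt.shape[0]
    best = 1e9
    best_j = -1
    e = np.full((m, t), 1e9)
    for i in range(m):
        for j in range(t):
            pt = pair_type[mir[i], tgt[j]]
            if pt < 0:
                continue
            cell = init  # duplex may start at this pair
            amax = min(i, MAX_LOOP)
            for a in range(amax + 1):
                ip = i - 1 - a
                if ip < 0:
                    break
                bmax = min(t - 1 - j, MAX_LOOP - a)
                for b in range(bmax + 1):
                    jp = j + 1 + b
                    if jp >= t:
                        break
                    prev = e[ip, jp]
                    if prev >= 1e9:
                        continue
                    ptp = pair_type[mir[ip], tgt[jp]]
                    if a == 0 and b == 0:
                        # reversed inner pair: (tgt[j], mir[i])
                        step = stack[ptp, pair_type[tgt[j], mir[i]]]
                    elif a == 0 or b == 0:
                        step = bulge[a + b]
                    else:
                        asym = abs(a - b) * ninio_per_nt
                        if asym > ninio_max:
                            asym = ninio_max
                        step = internal[a + b] + asym
                    if prev + step < cell:
                        cell = prev + step
            e[i, j] = cell
            if cell < best:
                best = cell
                best_j = j
    return best, best_j


def duplex_mfe(mirna_seq: str, target_seq: str) -> tuple[float, int]:
    """Minimum free energy of the miRNA:target duplex.

    Returns ``(mfe, best_site_start)`` with mfe in kcal/mol (<= 0; 0 means
    no stable duplex) and best_site_start the 1-based target position of
    the 5'-most paired target nucleotide of the optimal duplex (0 when no
    duplex). T and U are treated equivalently in both inputs.
    """
    mir = _normalize(mirna_seq, "miRNA")
    tgt = _normalize(target_seq, "target")
    if not mir or not tgt:
        raise ValueError("sequences must be non-empty")
    p = load_params()
    mfe, best_j = _duplex_core(
        np.array([_NT[c] for c in mir], dtype=np.int64),
        np.array([_NT[c] for c in tgt], dtype=np.int64),
        p.stack,
        p.bulge,
        p.internal,
        p.ninio_per_nt,
        p.ninio_max,
        p.init,
        _PAIR_TYPE,
    )
    if mfe >= 0 or best_j < 0:
        return 0.0, 0
    return float(round(mfe, 10)), int(best_j) + 1


@dataclass
class DuplexRecord:
    mirna_id: str
    transcript_id: str
    gene_id: str
    mfe: float
    best_site_start: int
    gene_avg_mfe: float = float("nan")
    passes_cutoff: bool = False


def gene_average_mfe(
    records: list[DuplexRecord], mfe_cutoff: float = MFE_CUTOFF
) -> list[DuplexRecord]:
    """Fill per-gene average mfe and the strict < cutoff pass flag in place."""
    by_gene: dict[tuple[str, str], list[DuplexRecord]] = {}
    for rec in records:
        by_gene.setdefault((rec.mirna_id, rec.gene_id), []).append(rec)
    for recs in by_gene.values():
        avg = float(np.mean([r.mfe for r in recs]))
        for r in recs:
            r.gene_avg_mfe = avg
            r.passes_cutoff = avg < mfe_cutoff
    return records


def duplex_table(records: list[DuplexRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])
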