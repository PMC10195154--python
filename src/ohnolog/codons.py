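"""Codon tables used by the sequence simulator and the Ks/Ka estimator.

Synonymous/nonsynonymous site fractions follow the Nei-Gojobori counting
convention: for each codon, each of the nine single-base changes is
classified by whether it preserves the encoded amino acid. Changes creating
a stop codon are counted as nonsynonymous for site counting but are never
applied by the simulator and are skipped when enumerating substitution
paths between observed codons.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

BASES = "TCAG"
CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

_table = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_table.stop_codons)
AA = {c: ("*" if c in STOP_CODONS else _table.forward_table[c]) for c in CODONS}

NON_STOP = [i for i, c in enumerate(CODONS) if c not in STOP_CODONS]

# Single-base neighbours, classified.
SYN_ALTS: list[list[int]] = [[] for _ in CODONS]
NONSYN_ALTS: list[list[int]] = [[] for _ in CODONS]  # excludes stops
SYN_SITES = np.zeros(64)
NONSYN_SITES = np.zeros(64)

for _i, _c in enumerate(CODONS):
    if _c in STOP_CODONS:
        continue
    n_syn = 0
    for _pos in range(3):
        for _b in BASES:
            if _b == _c[_pos]:
                continue
            _alt = _c[:_pos] + _b + _c[_pos + 1 :]
            _j = CODON_INDEX[_alt]
            if AA[_alt] == AA[_c]:
                SYN_ALTS[_i].append(_j)
                n_syn += 1
            elif _alt not in STOP_CODONS:
                NONSYN_ALTS[_i].append(_j)
    SYN_SITES[_i] = n_syn / 3.0
    NONSYN_SITES[_i] = 3.0 - n_syn / 3.0


def encode_cds(cds: str) -> np.ndarray:
    """CDS string -> array of codon indices."""
    if len(cds) % 3:
        raise ValueError("CDS length must be a multiple of 3")
    try:
        return np.array(
            [CODON_INDEX[cds[i : i + 3]] for i in range(0, len(cds), 3)], dtype=np.int16
        )
    except KeyError as exc:  # pragma: no cover - input validation
        raise ValueError(f"invalid codon in CDS: {exc}") from exc


def decode_cds(codons: np.ndarray) -> str:
    return "".join(CODONS[i] for i in codons)


def translate(codons: np.ndarray) -> str:
    return "".join(AA[CODONS[i]] for i in codons)


def _codon_path_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts over all
    substitution orderings between two codons, skipping paths through
    stop codons (all-stop path sets fall back to including them)."""
    positions = [p for p in range(3) if c1[p] != c2[p]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(positions):
        cur = c1
        syn = non = 0.0
        via_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != c2:
                via_stop = True
            if AA[nxt] == AA[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        paths.append((via_stop, syn, non))
    valid = [(s, n) for via, s, n in paths if not via]
    if not valid:
        valid = [(s, n) for _, s, n in paths]
    syn = sum(s for s, _ in valid) / len(valid)
    non = sum(n for _, n in valid) / len(valid)
    return syn, non


# cache: (codon_idx1, codon_idx2) -> (syn_diffs, nonsyn_diffs)
_PATH_CACHE: dict[tuple[int, int], tuple[float, float]] = {}


def path_counts(i: int, j: int) -> tuple[float, float]:
    key = (i, j) if i <= j else (j, i)
    out = _PATH_CACHE.get(key)
    if out is None:
        out = _codon_path_counts(CODONS[key[0]], CODONS[key[1]])
        _PATH_CACHE[key] = out
    return out
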