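"""RNA folding backends for the locus secondary-structure feature.

Two backends compute a stability score for the genomic region around a
locus: ``vienna`` calls RNAfold (minimum free energy, kcal/mol) through
the ViennaRNA python bindings; ``nussinov`` is a base-pair-maximisation
dynamic program returning -(maximum number of pairs) -- a documented
proxy that is monotone with fold stability but not an energy.
"""

from __future__ import annotations

from functools import lru_cache

#: Allowed pairs: Watson-Crick plus the G.U wobble (DNA alphabet, T == U).
_PAIRS = frozenset(
    [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")]
)

MIN_HAIRPIN_LOOP = 3


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


def nussinov_max_pairs(seq: str, min_loop: int = MIN_HAIRPIN_LOOP) -> int:
    """Maximum number of non-crossing base pairs in ``seq``.

    Standard O(n^3) interval dynamic program; positions i and j may pair
    only when ``j - i > min_loop`` (at least ``min_loop`` unpaired bases
    enclosed by a hairpin). N bases never pair.
    """
    s = seq.upper().replace("U", "T")
    n = len(s)
    if n == 0:
        return 0
    M = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i + 1][j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if can_pair(s[i], s[k]):
                    left = M[i + 1][k - 1] if k - 1 > i else 0
                    right = M[k + 1][j] if k + 1 <= j else 0
                    cand = 1 + left + right
                    if cand > best:
                        best = cand
            M[i][j] = best
    return M[0][n - 1]


def nussinov_energy(seq: str, min_loop: int = MIN_HAIRPIN_LOOP) -> float:
    """Folding proxy score: minus the maximum pair count (lower = more stable)."""
    return -float(nussinov_max_pairs(seq, min_loop))


@lru_cache(maxsize=1)
def _vienna_module():
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise RuntimeError(
            "ViennaRNA python bindings are not available; use the 'nussinov' "
            "or 'table' MFE backend instead"
        ) from exc
    return RNA


def vienna_available() -> bool:
    try:
        _vienna_module()
        return True
    except RuntimeError:
        return False


def vienna_mfe(seq: str) -> float:
    """Minimum free energy (kcal/mol) of ``seq`` from RNAfold with default parameters."""
    RNA = _vienna_module()
    rna = seq.upper().replace("T", "U")
    _structure, mfe = RNA.fold(rna)
    return float(mfe)
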