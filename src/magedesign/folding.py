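"""Secondary-structure evaluators for oligo optimization.

Stable self-folding of an ssDNA oligo lowers recombineering efficiency, so
the oligo engine shifts the design frame to maximize the folding minimum
free energy (MFE, kcal/mol; <= 0, with 0 meaning unstructured).  Two
evaluators are provided behind one interface:

* :class:`ViennaFoldingEvaluator` — the production backend, delegating to
  the ViennaRNA ``fold`` routine (nearest-neighbor model at 37 C).
* :class:`ToyFoldingEvaluator` — a deterministic Nussinov-style maximum
  complementary-pairing score (-1 per Watson-Crick pair, hairpin loops of
  at least 3 unpaired bases), used in tests and large sweeps.
"""

from __future__ import annotations

from typing import Callable, Protocol

import numpy as np
from numba import njit

VALID = set("ACGT")


class FoldingError(ValueError):
    pass


class FoldingEvaluator(Protocol):
    name: str

    def evaluate(self, sequence: str) -> float: ...


def _check(sequence: str) -> None:
    if not sequence:
        raise FoldingError("cannot fold an empty sequence")
    bad = set(sequence) - VALID
    if bad:
        raise FoldingError(f"invalid characters for folding: {sorted(bad)}")


_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@njit(cache=True)
def _nussinov_pairs(seq: np.ndarray, min_loop: int) -> int:
    """Maximum number of nested A/T, G/C pairs with hairpin loop >= min_loop."""
    n = seq.shape[0]
    m = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = m[i, j - 1]
            for k in range(i, j - min_loop):
                # complementary iff codes sum to 3 (A=0/T=3, C=1/G=2)
                if seq[k] + seq[j] == 3:
                    left = m[i, k - 1] if k > i else 0
                    inner = m[k + 1, j - 1] if k + 1 <= j - 1 else 0
                    cand = left + 1 + inner
                    if cand > best:
                        best = cand
            m[i, j] = best
    return int(m[0, n - 1])


class ToyFoldingEvaluator:
    """Nussinov maximum-pairing score: -1 kcal/mol per pair, loop min 3."""

    name = "toy-nussinov"

    def __init__(self, min_loop: int = 3):
        self.min_loop = min_loop

    def evaluate(self, sequence: str) -> float:
        _check(sequence)
        if len(sequence) < self.min_loop + 2:
            return 0.0
        encoded = np.array([_ENCODE[b] for b in sequence], dtype=np.int8)
        return -float(_nussinov_pairs(encoded, self.min_loop))


class ViennaFoldingEvaluator:
    """MFE folding via the ViennaRNA package (DNA sequence folded as-is)."""

    name = "viennarna-fold"

    def __init__(self, temperature: float = 37.0):
        import RNA  # deferred: optional backend

        self._RNA = RNA
        md = RNA.md()
        md.temperature = temperature
        self._md = md
        self.temperature = temperature

    def evaluate(self, sequence: str) -> float:
        _check(sequence)
        fc = self._RNA.fold_compound(sequence, self._md)
        _, mfe = fc.mfe()
        return min(float(mfe), 0.0)


class UniformFoldingEvaluator:
    """Every sequence scores 0; useful to exercise tie-breaking."""

    name = "uniform"

    def evaluate(self, sequence: str) -> float:
        _check(sequence)
        return 0.0


def default_evaluator() -> FoldingEvaluator:
    """ViennaRNA when importable, otherwise the toy evaluator."""
    try:
        return ViennaFoldingEvaluator()
    except ImportError:
        return ToyFoldingEvaluator()


def fold_mfe(evaluator: FoldingEvaluator, sequence: str) -> float:
    """Folding MFE of ``sequence`` under ``evaluator`` (kcal/mol, <= 0)."""
    return evaluator.evaluate(sequence)
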