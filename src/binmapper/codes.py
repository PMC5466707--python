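"""Integer codes and symbols for per-SNP observations and smoothed genotype calls.

Observations record the parental origin supported by the reads at one SNP in one
RIL; smoothed calls use the a/b/h/- convention of bin-map figures, where ``a``
is the paternal (P1) genotype, ``b`` the maternal (P2) genotype, ``h``
heterozygous and ``-`` no call.
"""

from __future__ import annotations

import numpy as np

# Observation codes (ObservationMatrix entries).
MISSING = 0
P1 = 1
P2 = 2
HET = 3

# Smoothed-call codes (GenotypeTrack / bin genotype columns).
NOCALL = 0
A = 1
B = 2
H = 3

CALL_SYMBOLS = {NOCALL: "-", A: "a", B: "b", H: "h"}
SYMBOL_CODES = {v: k for k, v in CALL_SYMBOLS.items()}

OBS_SYMBOLS = {MISSING: ".", P1: "0", P2: "1", HET: "h"}


def calls_to_symbols(calls: np.ndarray) -> np.ndarray:
    """Map an integer call array to the a/b/h/- symbol alphabet."""
    lut = np.array(["-", "a", "b", "h"])
    return lut[np.asarray(calls, dtype=np.int64)]


def symbols_to_calls(symbols) -> np.ndarray:
    """Inverse of :func:`calls_to_symbols`."""
    arr = np.asarray(symbols)
    out = np.zeros(arr.shape, dtype=np.int8)
    for sym, code in SYMBOL_CODES.items():
        out[arr == sym] = code
    return out


def swap_parents(codes: np.ndarray) -> np.ndarray:
    """Swap P1<->P2 (equivalently a<->b); h and missing are unchanged."""
    out = np.array(codes, copy=True)
    one = codes == 1
    out[codes == 2] = 1
    out[one] = 2
    return out
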