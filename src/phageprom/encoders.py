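"""Ten DNA feature-encoding schemes behind a shared physicochemical backend.

Two families:

* positional matrices fed to the CNN — ``onehot`` (99 x 4) and ``ncp``
  (99 x 3), zero-padded to the fixed 99-row model input;
* composition vectors fed to the baseline models — ``kmer``, ``pseeiip``,
  ``psednc``, ``pseknc``, ``pcpsednc``, ``pcpsetnc``, ``dacc`` and ``moran``.

The pseudo-composition (Pse*) encoders combine oligonucleotide frequencies
with lambda sequence-order correlation factors built from physicochemical
index profiles, weighted by ``w``; the covariance encoders (DAC/DCC/DACC) and
Moran autocorrelation summarise the same profiles at lags 1..LAG. All index
tables are standardized to mean 0 / population SD 1 over their oligonucleotides
before use.

Composition encodings are computed on the unpadded sequence (zero-fill would
corrupt frequency statistics); windows containing ``N`` are excluded from
counts and correlation terms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from typing import Callable

import numpy as np

from .sequence_io import DataError

BASES = "ACGT"
DINUCLEOTIDES = tuple("".join(p) for p in itertools.product(BASES, repeat=2))
TRINUCLEOTIDES = tuple("".join(p) for p in itertools.product(BASES, repeat=3))

#: electron-ion interaction pseudopotential per nucleotide (Nair values)
EIIP = {"A": 0.1260, "C": 0.1340, "G": 0.0806, "T": 0.1335}

MODEL_INPUT_LENGTH = 99


# ---------------------------------------------------------------------------
# physicochemical index sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhysicochemicalIndexSet:
    """Named di- or trinucleotide property tables.

    ``table`` maps each oligonucleotide to ``{index_name: value}``; di tables
    must cover all 16 dinucleotides, tri tables all 64 trinucleotides.
    """

    name: str
    order: str  # 'di' | 'tri'
    table: dict[str, dict[str, float]]
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.order not in ("di", "tri"):
            raise DataError(f"order must be 'di' or 'tri', got {self.order!r}")
        expected = DINUCLEOTIDES if self.order == "di" else TRINUCLEOTIDES
        missing = set(expected) - set(self.table)
        if missing:
            raise DataError(
                f"index set {self.name!r} missing oligonucleotides: "
                f"{sorted(missing)[:4]}..."
            )
        names = {tuple(sorted(v)) for v in self.table.values()}
        if len(names) != 1:
            raise DataError(f"index set {self.name!r}: ragged index names")

    @property
    def oligos(self) -> tuple[str, ...]:
        return DINUCLEOTIDES if self.order == "di" else TRINUCLEOTIDES

    @property
    def index_names(self) -> tuple[str, ...]:
        first = self.table[self.oligos[0]]
        return tuple(first)

    @property
    def n_indices(self) -> int:
        return len(self.index_names)

    def matrix(self) -> np.ndarray:
        """(n_oligos, n_indices) value matrix in lexicographic oligo order."""
        return np.array(
            [[self.table[o][i] for i in self.index_names] for o in self.oligos],
            dtype=float,
        )


def standardize_indices(raw: PhysicochemicalIndexSet) -> PhysicochemicalIndexSet:
    """Map each index to mean 0 and population SD 1 across its oligonucleotides.

    Idempotent; raises :class:`DataError` naming any constant index.
    """
    mat = raw.matrix()
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0)  # population SD
    for j, name in enumerate(raw.index_names):
        if sd[j] < 1e-12:
            raise DataError(
                f"index {name!r} in set {raw.name!r} is constant; "
                "cannot standardize"
            )
    std = (mat - mu) / sd
    table = {
        o: {n: float(std[i, j]) for j, n in enumerate(raw.index_names)}
        for i, o in enumerate(raw.oligos)
    }
    return replace(raw, table=table, standardized=True)


def _load_table(filename: str, order: str, name: str) -> PhysicochemicalIndexSet:
    text = (
        resources.files("phageprom").joinpath("data", filename).read_text()
    )
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    header = lines[0].split("\t")[1:]
    table: dict[str, dict[str, float]] = {}
    for ln in lines[1:]:
        parts = ln.split("\t")
        table[parts[0]] = {h: float(v) for h, v in zip(header, parts[1:])}
    return PhysicochemicalIndexSet(name=name, order=order, table=table)


@lru_cache(maxsize=None)
def dinucleotide_indices_6() -> PhysicochemicalIndexSet:
    """Six standardized B-DNA step parameters (twist/tilt/roll/shift/slide/rise)."""
    return standardize_indices(
        _load_table("dinucleotide_indices_6.tsv", "di", "dinucleotide-6")
    )


@lru_cache(maxsize=None)
def dinucleotide_indices_38() -> PhysicochemicalIndexSet:
    """38-index dinucleotide set (synthetic stand-in; see the data file header)."""
    return standardize_indices(
        _load_table(
            "dinucleotide_indices_38_synthetic.tsv", "di", "dinucleotide-38-synthetic"
        )
    )


@lru_cache(maxsize=None)
def trinucleotide_indices_6() -> PhysicochemicalIndexSet:
    """Six standardized trinucleotide indices derived from authentic constants."""
    return standardize_indices(
        _load_table("trinucleotide_indices_6.tsv", "tri", "trinucleotide-6")
    )


@dataclass(frozen=True)
class EncoderParams:
    """Tunable parameters shared by the composition encoders.

    ``lam`` is the highest counted correlation rank (lambda), ``w`` the weight
    factor in [0, 1], ``max_lag`` the maximum lag for covariance/Moran
    encoders, ``k`` the tuple size for kmer/PseKNC. ``index_set`` overrides
    the per-encoder default physicochemical table.
    """

    lam: int = 2
    w: float = 0.1
    max_lag: int = 2
    k: int = 3
    index_set: PhysicochemicalIndexSet | None = None

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise DataError(f"lam must be >= 0, got {self.lam}")
        if not 0 <= self.w <= 1:
            raise DataError(f"w must be in [0, 1], got {self.w}")
        if self.max_lag < 1:
            raise DataError(f"max_lag must be >= 1, got {self.max_lag}")
        if self.k < 1:
            raise DataError(f"k must be >= 1, got {self.k}")

    def indices(self, default: Callable[[], PhysicochemicalIndexSet], order: str
                ) -> PhysicochemicalIndexSet:
        idx = self.index_set if self.index_set is not None else default()
        if idx.order != order:
            raise DataError(
                f"encoder needs a {order!r} index set, got {idx.order!r}"
            )
        return idx if idx.standardized else standardize_indices(idx)


# ---------------------------------------------------------------------------
# positional encodings
# ---------------------------------------------------------------------------

def pad_positional(m: np.ndarray, target_rows: int = MODEL_INPUT_LENGTH) -> np.ndarray:
    """Zero-fill a positional matrix to ``target_rows`` rows (appended rows)."""
    if m.ndim != 2:
        raise DataError(f"expected a 2-D matrix, got ndim={m.ndim}")
    if m.shape[0] > target_rows:
        raise DataError(f"matrix has {m.shape[0]} rows > target {target_rows}")
    out = np.zeros((target_rows, m.shape[1]), dtype=float)
    out[: m.shape[0]] = m
    return out


_ONE_HOT = {"A": (1, 0, 0, 0), "C": (0, 1, 0, 0), "G": (0, 0, 1, 0), "T": (0, 0, 0, 1)}
_NCP = {"A": (1, 1, 1), "C": (1, 0, 0), "G": (0, 1, 0), "T": (0, 0, 1)}


def encode_one_hot(seq: str, pad_to: int = MODEL_INPUT_LENGTH) -> np.ndarray:
    """Per-position 4-channel indicator matrix, channel order (A, C, G, T).

    ``N`` encodes as an all-zero row; output is zero-padded to ``pad_to`` rows.
    """
    m = np.array([_ONE_HOT.get(b, (0, 0, 0, 0)) for b in seq], dtype=float)
    m = m.reshape(len(seq), 4)
    return pad_positional(m, pad_to)


def encode_ncp(seq: str, pad_to: int = MODEL_INPUT_LENGTH) -> np.ndarray:
    """Nucleotide chemical property triples (b, c, p) per base.

    b: amino group (A, C); c: purine ring (A, G); p: weak hydrogen bond (A, T).
    ``N`` encodes as an all-zero row.
    """
    m = np.array([_NCP.get(b, (0, 0, 0)) for b in seq], dtype=float)
    m = m.reshape(len(seq), 3)
    return pad_positional(m, pad_to)


# ---------------------------------------------------------------------------
# composition helpers
# ---------------------------------------------------------------------------

def _window_ids(seq: str, k: int) -> np.ndarray:
    """Lexicographic oligo index per window; -1 for windows containing N."""
    code = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}.get(b, -1) for b in seq])
    n_win = len(seq) - k + 1
    if n_win < 1:
        raise DataError(f"sequence of length {len(seq)} too short for k={k}")
    ids = np.zeros(n_win, dtype=int)
    valid = np.ones(n_win, dtype=bool)
    for o in range(k):
        sub = code[o : o + n_win]
        ids = ids * 4 + np.where(sub < 0, 0, sub)
        valid &= sub >= 0
    ids[~valid] = -1
    return ids


def _tuple_frequencies(seq: str, k: int) -> np.ndarray:
    ids = _window_ids(seq, k)
    valid = ids[ids >= 0]
    if valid.size == 0:
        raise DataError("no ambiguity-free windows in sequence")
    counts = np.bincount(valid, minlength=4**k).astype(float)
    return counts / valid.size


def encode_kmer(seq: str, k: int = 3) -> np.ndarray:
    """Overlapping k-tuple frequencies in lexicographic order (sum to 1)."""
    if len(seq) < k:
        raise DataError(f"sequence length {len(seq)} < k={k}")
    return _tuple_frequencies(seq, k)


def encode_pseeiip(seq: str, mode: str = "sum") -> np.ndarray:
    """Trinucleotide frequencies weighted by their EIIP value (dim 64).

    ``mode='sum'`` uses the summed mononucleotide EIIP of the triplet (the
    common convention); ``mode='mean'`` divides that sum by three.
    """
    if mode not in ("sum", "mean"):
        raise DataError(f"mode must be 'sum' or 'mean', got {mode!r}")
    if len(seq) < 3:
        raise DataError(f"sequence length {len(seq)} < 3")
    f = _tuple_frequencies(seq, 3)
    weights = np.array([sum(EIIP[b] for b in t) for t in TRINUCLEOTIDES])
    if mode == "mean":
        weights = weights / 3.0
    return weights * f


def _profile(seq: str, idx: PhysicochemicalIndexSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-window standardized index values: (n_windows, n_indices), valid mask."""
    k = 2 if idx.order == "di" else 3
    ids = _window_ids(seq, k)
    mat = idx.matrix()
    prof = np.zeros((ids.size, mat.shape[1]))
    valid = ids >= 0
    prof[valid] = mat[ids[valid]]
    return prof, valid


def _theta_factors(
    prof: np.ndarray, valid: np.ndarray, lam: int
) -> np.ndarray:
    """Sequence-order correlation factors theta_1..theta_lam.

    theta_j averages the squared-difference correlation
    Theta(i, i+j) = mean_u (P_u[i] - P_u[i+j])^2 over all window pairs at
    rank j (terms with an ambiguous window are dropped from the average).
    """
    n = prof.shape[0]
    thetas = np.zeros(lam)
    for j in range(1, lam + 1):
        if n - j < 1:
            raise DataError(
                f"lam/rank {j} too large for {n} sequence windows"
            )
        pair_valid = valid[: n - j] & valid[j:]
        if not pair_valid.any():
            raise DataError(f"no valid window pairs at rank {j}")
        diff = prof[: n - j] - prof[j:]
        theta_terms = np.mean(diff**2, axis=1)
        thetas[j - 1] = theta_terms[pair_valid].mean()
    return thetas


def _pse_vector(freqs: np.ndarray, thetas: np.ndarray, w: float) -> np.ndarray:
    denom = freqs.sum() + w * thetas.sum()
    return np.concatenate([freqs, w * thetas]) / denom


def encode_psednc(seq: str, p: EncoderParams | None = None) -> np.ndarray:
    """Pseudo dinucleotide composition: dim 16 + lambda, entries sum to 1.

    The first 16 entries are proportional to dinucleotide frequencies; the
    tail carries the w-weighted correlation factors built from the six
    standardized structural indices (overridable via ``p.index_set``).
    """
    p = p or EncoderParams()
    if len(seq) < p.lam + 2:
        raise DataError(f"need length >= lam+2 = {p.lam + 2}, got {len(seq)}")
    idx = p.indices(dinucleotide_indices_6, "di")
    freqs = _tuple_frequencies(seq, 2)
    prof, valid = _profile(seq, idx)
    thetas = _theta_factors(prof, valid, p.lam)
    return _pse_vector(freqs, thetas, p.w)


def encode_pcpsednc(seq: str, p: EncoderParams | None = None) -> np.ndarray:
    """Parallel-correlation PseDNC: as PseDNC but with the 38-index set."""
    p = p or EncoderParams()
    if p.index_set is None:
        p = replace(p, index_set=dinucleotide_indices_38())
    return encode_psednc(seq, p)


def encode_pcpsetnc(seq: str, p: EncoderParams | None = None) -> np.ndarray:
    """Parallel-correlation pseudo trinucleotide composition: dim 64 + lambda."""
    p = p or EncoderParams()
    if len(seq) < p.lam + 3:
        raise DataError(f"need length >= lam+3 = {p.lam + 3}, got {len(seq)}")
    idx = p.indices(trinucleotide_indices_6, "tri")
    freqs = _tuple_frequencies(seq, 3)
    prof, valid = _profile(seq, idx)
    thetas = _theta_factors(prof, valid, p.lam)
    return _pse_vector(freqs, thetas, p.w)


def encode_pseknc(seq: str, p: EncoderParams | None = None) -> np.ndarray:
    """Pseudo k-tuple composition: dim 4^k + lambda, entries sum to 1.

    k-tuple frequencies are normalized to sum 1; the correlation factors are
    computed on dinucleotide profiles regardless of k.
    """
    p = p or EncoderParams()
    if len(seq) < max(p.k, p.lam + 2):
        raise DataError(
            f"need length >= max(k, lam+2) = {max(p.k, p.lam + 2)}, got {len(seq)}"
        )
    idx = p.indices(dinucleotide_indices_6, "di")
    freqs = _tuple_frequencies(seq, p.k)
    prof, valid = _profile(seq, idx)
    thetas = _theta_factors(prof, valid, p.lam)
    return _pse_vector(freqs, thetas, p.w)


# ---------------------------------------------------------------------------
# covariance & autocorrelation encodings
# ---------------------------------------------------------------------------

def _masked_mean(x: np.ndarray, mask: np.ndarray) -> float:
    return float(x[mask].mean())


def encode_dac(seq: str, p: EncoderParams | None = None) -> np.ndarray:
    """Dinucleotide auto-covariance at lags 1..LAG (dim N x LAG).

    For each index u, DAC(u, lag) averages the product of deviations from the
    sequence-wide mean profile value at windows separated by ``lag``.
    Ordered index-major: (u1 lag1, u1 lag2, ..., uN lagLAG).
    """
    p = p or EncoderParams()
    if len(seq) < p.max_lag + 2:
        raise DataError(
            f"need length >= max_lag+2 = {p.max_lag + 2}, got {len(seq)}"
        )
    idx = p.indices(dinucleotide_indices_6, "di")
    prof, valid = _profile(seq, idx)
    n = prof.shape[0]
    out = []
    for u in range(prof.shape[1]):
        x = prof[:, u]
        mean_u = _masked_mean(x, valid)
        for lag in range(1, p.max_lag + 1):
            pv = valid[: n - lag] & valid[lag:]
            terms = (x[: n - lag] - mean_u) * (x[lag:] - mean_u)
            out.append(terms[pv].sum() / pv.sum())
    return np.array(out)


def encode_dcc(seq: str, p: EncoderParams | None = None) -> np.ndarray:
    """Dinucleotide cross covariance for ordered index pairs u1 != u2.

    Dim N x (N-1) x LAG, ordered pair-major in (u1, u2) lexicographic order.
    """
    p = p or EncoderParams()
    if len(seq) < p.max_lag + 2:
        raise DataError(
            f"need length >= max_lag+2 = {p.max_lag + 2}, got {len(seq)}"
        )
    idx = p.indices(dinucleotide_indices_6, "di")
    prof, valid = _profile(seq, idx)
    n = prof.shape[0]
    means = [_masked_mean(prof[:, u], valid) for u in range(prof.shape[1])]
    out = []
    for u1 in range(prof.shape[1]):
        for u2 in range(prof.shape[1]):
            if u1 == u2:
                continue
            for lag in range(1, p.max_lag + 1):
                pv = valid[: n - lag] & valid[lag:]
                terms = (prof[: n - lag, u1] - means[u1]) * (
                    prof[lag:, u2] - means[u2]
                )
                out.append(terms[pv].sum() / pv.sum())
    return np.array(out)


def encode_dacc(seq: str, p: EncoderParams | None = None) -> np.ndarray:
    """Concatenated DAC then DCC: total dimension N^2 x LAG."""
    return np.concatenate([encode_dac(seq, p), encode_dcc(seq, p)])


def encode_moran(seq: str, p: EncoderParams | None = None) -> np.ndarray:
    """Moran spatial autocorrelation of each index profile at lags 1..LAG.

    I(u, lag) = [sum (x_i - xbar)(x_{i+lag} - xbar) / (M - lag)] /
                [sum (x_i - xbar)^2 / M]  over the M = L-1 dinucleotide
    windows; a zero-variance profile yields 0. Dim N x LAG, index-major.
    """
    p = p or EncoderParams()
    if len(seq) < p.max_lag + 2:
        raise DataError(
            f"need length >= max_lag+2 = {p.max_lag + 2}, got {len(seq)}"
        )
    idx = p.indices(dinucleotide_indices_6, "di")
    prof, valid = _profile(seq, idx)
    n = prof.shape[0]
    out = []
    for u in range(prof.shape[1]):
        x = prof[:, u]
        xbar = _masked_mean(x, valid)
        var = float(((x[valid] - xbar) ** 2).mean())
        for lag in range(1, p.max_lag + 1):
            if var < 1e-30:
                out.append(0.0)
                continue
            pv = valid[: n - lag] & valid[lag:]
            terms = (x[: n - lag] - xbar) * (x[lag:] - xbar)
            num = terms[pv].sum() / pv.sum()
            out.append(num / var)
    return np.array(out)


# ---------------------------------------------------------------------------
# scheme registry
# ---------------------------------------------------------------------------

#: schemes producing positional matrices (CNN input); all others yield vectors
POSITIONAL_SCHEMES = ("onehot", "ncp")

ENCODERS: dict[str, Callable[..., np.ndarray]] = {
    "onehot": lambda seq, p=None: encode_one_hot(seq),
    "ncp": lambda seq, p=None: encode_ncp(seq),
    "kmer": lambda seq, p=None: encode_kmer(seq, (p or EncoderParams()).k),
    "pseeiip": lambda seq, p=None: encode_pseeiip(seq),
    "psednc": encode_psednc,
    "pseknc": encode_pseknc,
    "dacc": encode_dacc,
    "pcpsednc": encode_pcpsednc,
    "pcpsetnc": encode_pcpsetnc,
    "moran": encode_moran,
}


def encode_sequence(seq: str, scheme: str, params: EncoderParams | None = None
                    ) -> np.ndarray:
    if scheme not in ENCODERS:
        raise DataError(
            f"unknown encoding scheme {scheme!r}; choose from {sorted(ENCODERS)}"
        )
    return ENCODERS[scheme](seq, params)


def encode_dataset(
    seqs: list[str],
    scheme: str,
    params: EncoderParams | None = None,
    flatten: bool = False,
) -> np.ndarray:
    """Encode a list of sequences; stacked (n, ...) array.

    Positional schemes yield (n, 99, channels); with ``flatten=True`` matrices
    are flattened row-major for vector-input models.
    """
    arrs = [encode_sequence(s, scheme, params) for s in seqs]
    out = np.stack(arrs)
    if flatten and out.ndim == 3:
        out = out.reshape(out.shape[0], -1)
    return out
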