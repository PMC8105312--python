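"""Pairwise molecular-evolution rates for aligned coding sequences.

Three layers:

* **NG86 counting** — expected synonymous (S) and nonsynonymous (N)
  sites from single-nucleotide mutational neighbours of each codon,
  observed differences averaged over minimal substitution pathways,
  and Jukes–Cantor correction of the proportions to dS (Ks) and
  dN (Ka).
* **GY94 maximum likelihood** — the Goldman–Yang codon substitution
  model over the 61 sense codons, parameterised by branch length t
  (expected substitutions per codon), transition/transversion ratio
  kappa and dN/dS ratio omega, fitted to a sequence pair by maximising
  the pairwise likelihood; a likelihood-ratio test of omega = 1
  against chi-square with one degree of freedom.
* **Ks dating** — divergence time T = Ks / (2r) for a substitution
  rate r per site per year.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from Bio.Data import CodonTable

__all__ = [
    "SENSE_CODONS",
    "STOP_CODONS",
    "CodonPair",
    "PairwiseRates",
    "MLFit",
    "LRTResult",
    "DivergenceEstimate",
    "clean_alignment",
    "ng86",
    "build_rate_matrix",
    "transition_matrix",
    "f3x4_frequencies",
    "pair_log_likelihood",
    "gy94_fit",
    "lrt",
    "divergence_time",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard genetic code
STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
_AA = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}
_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
_NTS = "ACGT"
_PURINES = {"A", "G"}

# default per-site-per-year substitution rate for grass divergence dating
DEFAULT_CLOCK_RATE = 6.5e-9

# parameter bounds for the ML fit
T_BOUNDS = (1e-6, 50.0)
KAPPA_BOUNDS = (1e-2, 1e2)
OMEGA_BOUNDS = (1e-4, 20.0)


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


def _pair_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Static single-difference / transition / synonymous masks, 61x61."""
    n = len(SENSE_CODONS)
    single = np.zeros((n, n), dtype=bool)
    transition = np.zeros((n, n), dtype=bool)
    synonymous = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) == 1:
                single[i, j] = True
                transition[i, j] = _is_transition(*diffs[0])
                synonymous[i, j] = _AA[ci] == _AA[cj]
    return single, transition, synonymous


_SINGLE, _TRANSITION, _SYNONYMOUS = _pair_tables()


# ---------------------------------------------------------------------------
# alignment containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodonPair:
    """A gap-free pair of aligned coding sequences (no internal stops)."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise ValueError("aligned sequences must have equal length")
        if len(a) % 3 != 0:
            raise ValueError("length must be divisible by 3")
        if len(a) == 0:
            raise ValueError("empty alignment")
        for seq, name in ((a, "seq_a"), (b, "seq_b")):
            if set(seq) - set(_NTS):
                raise ValueError(f"{name} contains non-ACGT characters; clean first")
            for k in range(0, len(seq), 3):
                if seq[k : k + 3] in STOP_CODONS:
                    raise ValueError(f"{name} contains stop codon at nt {k}")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codons(self) -> list[tuple[str, str]]:
        return [
            (self.seq_a[k : k + 3], self.seq_b[k : k + 3])
            for k in range(0, len(self.seq_a), 3)
        ]


def clean_alignment(seq_a: str, seq_b: str) -> CodonPair:
    """Drop codon columns with gaps, ambiguity codes or stop codons.

    Mirrors the usual "cleandata" behaviour of codon-model software:
    a column is removed if either sequence's codon contains a non-ACGT
    character or translates to a stop.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    if len(a) % 3 != 0:
        raise ValueError("length must be divisible by 3")
    keep_a, keep_b = [], []
    for k in range(0, len(a), 3):
        ca, cb = a[k : k + 3], b[k : k + 3]
        if set(ca + cb) - set(_NTS):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        keep_a.append(ca)
        keep_b.append(cb)
    if not keep_a:
        raise ValueError("no clean codon columns remain after filtering")
    return CodonPair("".join(keep_a), "".join(keep_b))


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseRates:
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float  # Ks; may be +inf when saturated
    dN: float  # Ka; may be +inf when saturated
    omega: float | None  # dN/dS; None when dS == 0 or saturated
    saturated: bool = False


def _codon_site_counts(codon: str) -> float:
    """Synonymous site count of one codon (0..3, denominator 3/position).

    Each position contributes (synonymous single-nt changes)/3; changes
    to stop codons are not synonymous and therefore count toward N.
    """
    syn = 0.0
    aa = _AA[codon]
    for pos in range(3):
        for nt in _NTS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt not in STOP_CODONS and _AA[alt] == aa:
                syn += 1.0
    return syn / 3.0


def _path_steps(ca: str, cb: str) -> tuple[float, float]:
    """Average (syn, nonsyn) difference counts over minimal pathways.

    Pathways passing through a stop codon are excluded; if every
    pathway is blocked, all pathways are used with steps into or out of
    stop codons counted as nonsynonymous.
    """
    diff_pos = [p for p in range(3) if ca[p] != cb[p]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float, bool]:
        cur = ca
        syn = nonsyn = 0.0
        through_stop = False
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            if cur in STOP_CODONS or nxt in STOP_CODONS:
                through_stop = True
                nonsyn += 1.0
            elif _AA[cur] == _AA[nxt]:
                syn += 1.0
            else:
                nonsyn += 1.0
            cur = nxt
        return syn, nonsyn, through_stop

    paths = [walk(order) for order in itertools.permutations(diff_pos)]
    clean = [(s, n) for s, n, blocked in paths if not blocked]
    use = clean if clean else [(s, n) for s, n, _ in paths]
    s = sum(p[0] for p in use) / len(use)
    n = sum(p[1] for p in use) / len(use)
    return s, n


def _jc_correct(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return math.inf, True
    if p == 0.0:
        return 0.0, False
    return -0.75 * math.log1p(-4.0 * p / 3.0), False


def ng86(pair: CodonPair) -> PairwiseRates:
    """Nei–Gojobori (1986) synonymous/nonsynonymous rates for a pair."""
    s_a = s_b = 0.0
    sd = nd = 0.0
    for ca, cb in pair.codons():
        s_a += _codon_site_counts(ca)
        s_b += _codon_site_counts(cb)
        ds, dn = _path_steps(ca, cb)
        sd += ds
        nd += dn
    total = 3.0 * pair.n_codons
    s_sites = (s_a + s_b) / 2.0
    n_sites = total - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    d_s, sat_s = _jc_correct(ps)
    d_n, sat_n = _jc_correct(pn)
    saturated = sat_s or sat_n
    if saturated or d_s == 0.0:
        omega = None
    else:
        omega = d_n / d_s
    return PairwiseRates(
        S_sites=s_sites,
        N_sites=n_sites,
        Sd=sd,
        Nd=nd,
        pS=ps,
        pN=pn,
        dS=d_s,
        dN=d_n,
        omega=omega,
        saturated=saturated,
    )


# ---------------------------------------------------------------------------
# GY94 likelihood machinery
# ---------------------------------------------------------------------------


def build_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """GY94 instantaneous rate matrix Q over the 61 sense codons.

    q_ij = pi_j x kappa^[transition] x omega^[nonsynonymous] for
    single-nucleotide changes, 0 otherwise; diagonal sets rows to sum
    to zero; Q is scaled so -sum_i pi_i q_ii = 1, i.e. t is measured in
    expected substitutions per codon.
    """
    if kappa <= 0 or omega <= 0:
        raise ValueError("kappa and omega must be > 0")
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (61,) or (pi < 0).any() or not math.isclose(pi.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("pi must be a 61-codon probability vector")
    q = np.where(_SINGLE, np.tile(pi, (61, 1)), 0.0)
    q = q * np.where(_TRANSITION & _SINGLE, kappa, 1.0)
    q = q * np.where(_SINGLE & ~_SYNONYMOUS, omega, 1.0)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -np.sum(pi * np.diag(q))
    if scale <= 0:
        raise ValueError("degenerate rate matrix (check codon frequencies)")
    return q / scale


def transition_matrix(q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) via symmetric eigendecomposition.

    The GY94 chain is reversible, so D^{1/2} Q D^{-1/2} (D = diag(pi))
    is symmetric and a single `eigh` gives P(t) for any t.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    pi = np.asarray(pi, dtype=float)
    d = np.sqrt(np.maximum(pi, 1e-300))
    s = (q * d[:, None]) / d[None, :]
    s = (s + s.T) / 2.0  # symmetrise away rounding noise
    w, v = np.linalg.eigh(s)
    p = (v * np.exp(w * t)) @ v.T
    p = (p / d[:, None]) * d[None, :]
    return np.clip(p, 0.0, None)


def f3x4_frequencies(pair: CodonPair, floor: float = 1e-8) -> np.ndarray:
    """F3x4 codon frequencies from the concatenated pair.

    Nucleotide frequencies are estimated per codon position from both
    sequences; codon frequencies are their product renormalised over
    the 61 sense codons. A small floor keeps every sense codon
    reachable for the likelihood.
    """
    pos_freq = np.zeros((3, 4))
    for seq in (pair.seq_a, pair.seq_b):
        for k in range(0, len(seq), 3):
            for p in range(3):
                pos_freq[p, _NTS.index(seq[k + p])] += 1.0
    pos_freq /= pos_freq.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freq[0, _NTS.index(c[0])]
            * pos_freq[1, _NTS.index(c[1])]
            * pos_freq[2, _NTS.index(c[2])]
            for c in SENSE_CODONS
        ]
    )
    pi = np.maximum(pi, floor)
    return pi / pi.sum()


def equal_frequencies() -> np.ndarray:
    return np.full(61, 1.0 / 61.0)


def _pair_counts(pair: CodonPair) -> np.ndarray:
    counts = np.zeros((61, 61))
    for ca, cb in pair.codons():
        counts[_INDEX[ca], _INDEX[cb]] += 1.0
    return counts


def pair_log_likelihood(
    counts: np.ndarray, t: float, kappa: float, omega: float, pi: np.ndarray
) -> float:
    """Pairwise log-likelihood sum_sites log(pi_a P_{a->b}(t))."""
    q = build_rate_matrix(kappa, omega, pi)
    p = transition_matrix(q, pi, t)
    joint = pi[:, None] * p
    with np.errstate(divide="ignore"):
        logj = np.log(np.maximum(joint, 1e-300))
    return float(np.sum(counts * logj))


@dataclass(frozen=True)
class MLFit:
    t_hat: float
    kappa_hat: float
    omega_hat: float
    logL: float
    converged: bool
    omega_fixed: bool = False
    codon_freqs: np.ndarray | None = field(default=None, repr=False)
    diagnostics: dict = field(default_factory=dict, repr=False)


_STARTS = [
    (0.2, 2.0, 0.4),
    (1.0, 1.0, 1.0),
    (0.05, 5.0, 0.05),
    (2.0, 2.0, 3.0),
]


def gy94_fit(
    pair: CodonPair,
    fix_omega: float | None = None,
    freqs: str = "f3x4",
) -> MLFit:
    """Maximum-likelihood GY94 fit to a codon pair.

    Optimises (t, kappa, omega), or (t, kappa) with omega fixed, in log
    space with bound constraints, from several starting points; the fit
    with the best log-likelihood wins (ties toward smaller t).
    """
    if freqs == "f3x4":
        pi = f3x4_frequencies(pair)
    elif freqs == "equal":
        pi = equal_frequencies()
    else:
        raise ValueError("freqs must be 'f3x4' or 'equal'")
    counts = _pair_counts(pair)
    free_omega = fix_omega is None
    if not free_omega and fix_omega <= 0:
        raise ValueError("fixed omega must be > 0")

    def negll(logp: np.ndarray) -> float:
        t, kappa = math.exp(logp[0]), math.exp(logp[1])
        omega = math.exp(logp[2]) if free_omega else fix_omega
        return -pair_log_likelihood(counts, t, kappa, omega, pi)

    bounds = [tuple(np.log(T_BOUNDS)), tuple(np.log(KAPPA_BOUNDS))]
    if free_omega:
        bounds.append(tuple(np.log(OMEGA_BOUNDS)))

    best = None
    n_ok = 0
    for t0, k0, w0 in _STARTS:
        x0 = [math.log(t0), math.log(k0)] + ([math.log(w0)] if free_omega else [])
        res = optimize.minimize(negll, x0, method="L-BFGS-B", bounds=bounds)
        if not np.isfinite(res.fun):
            continue
        n_ok += int(res.success)
        cand = (res.fun, math.exp(res.x[0]), res)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        return MLFit(
            t_hat=math.nan,
            kappa_hat=math.nan,
            omega_hat=math.nan if free_omega else fix_omega,
            logL=math.nan,
            converged=False,
            omega_fixed=not free_omega,
            codon_freqs=pi,
            diagnostics={"n_successful_starts": 0},
        )
    _, _, res = best
    t_hat, kappa_hat = math.exp(res.x[0]), math.exp(res.x[1])
    omega_hat = math.exp(res.x[2]) if free_omega else float(fix_omega)
    return MLFit(
        t_hat=t_hat,
        kappa_hat=kappa_hat,
        omega_hat=omega_hat,
        logL=-float(res.fun),
        converged=n_ok > 0,
        omega_fixed=not free_omega,
        codon_freqs=pi,
        diagnostics={"n_successful_starts": n_ok, "n_starts": len(_STARTS)},
    )


# ---------------------------------------------------------------------------
# LRT and dating
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LRTResult:
    stat: float  # 2 (logL_free - logL_fixed), clamped at 0
    df: int
    p: float
    significant: bool  # p < 0.05


def lrt(free: MLFit, fixed: MLFit, alpha: float = 0.05) -> LRTResult:
    """Likelihood-ratio test of omega = 1 against the free-omega fit.

    The statistic 2(l_free - l_fixed) is compared to the upper tail of
    chi-square with one degree of freedom; omega = 1 is interior to the
    parameter space, so no boundary correction applies.
    """
    if not (free.converged and fixed.converged):
        raise ValueError("both fits must have converged")
    if not fixed.omega_fixed or not math.isclose(fixed.omega_hat, 1.0):
        raise ValueError("fixed fit must have omega fixed at 1")
    delta = free.logL - fixed.logL
    if delta < -1e-6:
        raise ValueError(
            f"free logL {free.logL:.6f} below fixed logL {fixed.logL:.6f}: "
            "optimizer failure (free model must dominate)"
        )
    stat = max(2.0 * delta, 0.0)
    p = float(stats.chi2.sf(stat, df=1))
    return LRTResult(stat=stat, df=1, p=p, significant=p < alpha)


@dataclass(frozen=True)
class DivergenceEstimate:
    mean_Ks: float
    rate: float  # substitutions per site per year
    time_years: float


def divergence_time(mean_ks: float, rate: float = DEFAULT_CLOCK_RATE) -> DivergenceEstimate:
    """Divergence time T = Ks / (2r) under a strict molecular clock.

    The factor 2 accounts for substitutions accumulating independently
    on both lineages since their split.
    """
    if mean_ks < 0:
        raise ValueError("mean Ks must be >= 0")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    return DivergenceEstimate(mean_Ks=mean_ks, rate=rate, time_years=mean_ks / (2.0 * rate))
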