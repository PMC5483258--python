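"""k-mer frequency spectrum and diploid genome-size estimation.

In a highly heterozygous diploid, k-mers from diverged (single-copy)
regions appear at the per-haplotype sequencing depth c while k-mers from
identical (two-copy) regions appear at 2c, so the spectrum of a read set
is bimodal.  The spectrum is fitted as a two-component negative-binomial
mixture with the diploid constraint (second mean exactly twice the
first); the genome size follows from dividing the total above-cutoff
k-mer mass by the single-copy depth, which counts fully diverged diploid
regions twice (the diploid span convention).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .io import encode_seq


@dataclass
class KmerSpectrum:
    k: int
    histogram: dict[int, int]  # frequency -> number of distinct canonical k-mers

    @property
    def total_kmer_instances(self) -> int:
        return sum(f * n for f, n in self.histogram.items())

    @property
    def total_distinct(self) -> int:
        return sum(self.histogram.values())

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        freqs = np.array(sorted(self.histogram), dtype=np.int64)
        counts = np.array([self.histogram[int(f)] for f in freqs], dtype=np.int64)
        return freqs, counts

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("frequency\tdistinct_kmers\n")
            for f in sorted(self.histogram):
                fh.write(f"{f}\t{self.histogram[f]}\n")


def count_kmers(reads, k: int = 21) -> KmerSpectrum:
    """Canonical k-mer spectrum of a read set.

    ``reads`` is an iterable of (read_id, sequence) pairs or plain
    sequences.  k must be odd (a canonical k-mer is then never its own
    reverse complement); windows containing N are skipped, and reads
    shorter than k are skipped with a warning.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if k > 31:
        raise ValueError("k larger than 31 not supported by 2-bit packing")
    chunks: list[np.ndarray] = []
    short_reads = 0
    for read in reads:
        seq = read[1] if isinstance(read, tuple) else read
        if len(seq) < k:
            short_reads += 1
            continue
        codes = encode_seq(seq)
        win = np.lib.stride_tricks.sliding_window_view(codes, k)
        valid = (win <= 3).all(axis=1)
        safe = np.where(win > 3, 0, win).astype(np.int64)
        fwd = np.zeros(win.shape[0], dtype=np.int64)
        rev = np.zeros(win.shape[0], dtype=np.int64)
        for t in range(k):
            fwd = fwd * 4 + safe[:, t]
            rev = rev * 4 + (3 - safe[:, k - 1 - t])
        chunks.append(np.minimum(fwd, rev)[valid])
    if short_reads:
        warnings.warn(f"{short_reads} reads shorter than k={k} skipped")
    if not chunks:
        return KmerSpectrum(k, {})
    kmers = np.concatenate(chunks)
    _, freq_per_kmer = np.unique(kmers, return_counts=True)
    freqs, n_distinct = np.unique(freq_per_kmer, return_counts=True)
    return KmerSpectrum(k, {int(f): int(n) for f, n in zip(freqs, n_distinct)})


# -------------------------------------------------------------- fitting --

def first_local_minimum(freqs: np.ndarray, counts: np.ndarray) -> int:
    """Error cutoff: first frequency where the histogram turns upward."""
    for i in range(len(freqs) - 1):
        if counts[i + 1] > counts[i]:
            return int(freqs[i])
    return int(freqs[0])


def _nb_logpmf(x: np.ndarray, mean: float, dispersion: float) -> np.ndarray:
    """Negative binomial log-pmf parameterized by mean and dispersion r
    (variance = mean + mean^2 / r).

    The dispersion is clamped to [1e-2, 1e4]; beyond that the distribution
    is numerically indistinguishable from (and unstable relative to) the
    Poisson limit."""
    r = float(np.clip(dispersion, 1e-2, 1e4))
    p = r / (r + mean)
    return (special.gammaln(x + r) - special.gammaln(r)
            - special.gammaln(x + 1) + r * np.log(p) + x * np.log1p(-p))


@dataclass
class SpectrumFit:
    mu_het: float                  # single-copy (heterozygous) peak depth
    dispersion: float
    weight_single: float           # mixture weight of the single-copy component
    fraction_single_copy: float
    fraction_two_copy: float
    genome_size_estimate: float    # diploid span, bp
    error_cutoff: int
    single_component: bool = False
    mu_unconstrained: tuple[float, float] | None = None
    log_likelihood: float = 0.0

    @property
    def mu_hom(self) -> float:
        return 2.0 * self.mu_het

    @property
    def peak_ratio_unconstrained(self) -> float | None:
        if self.mu_unconstrained is None:
            return None
        lo, hi = sorted(self.mu_unconstrained)
        return hi / lo if lo > 0 else None

    def to_json(self, path=None) -> str:
        data = {
            "mu_het": self.mu_het, "mu_hom": self.mu_hom,
            "dispersion": self.dispersion,
            "weight_single": self.weight_single,
            "fraction_single_copy": self.fraction_single_copy,
            "fraction_two_copy": self.fraction_two_copy,
            "genome_size_estimate": self.genome_size_estimate,
            "error_cutoff": self.error_cutoff,
            "single_component": self.single_component,
            "mu_unconstrained": self.mu_unconstrained,
            "peak_ratio_unconstrained": self.peak_ratio_unconstrained,
        }
        text = json.dumps(data, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _mixture_nll(params, freqs, counts, constrained: bool):
    # log-parameters clipped to keep optimizer excursions finite
    if constrained:
        log_mu, log_r, logit_w = np.clip(params, -30, 30)
        mu2 = 2.0 * np.exp(log_mu)
    else:
        log_mu, log_r, logit_w, log_mu2 = np.clip(params, -30, 30)
        mu2 = np.exp(log_mu2)
    mu1, r = np.exp(log_mu), np.exp(log_r)
    w = 1.0 / (1.0 + np.exp(-logit_w))
    with np.errstate(divide="ignore", invalid="ignore"):
        lp1 = _nb_logpmf(freqs, mu1, r) + np.log(w)
        lp2 = _nb_logpmf(freqs, mu2, r) + np.log1p(-w)
        ll = np.logaddexp(lp1, lp2)
    if not np.all(np.isfinite(ll)):
        return 1e18
    return -float(np.sum(counts * ll))


def fit_spectrum(spectrum: KmerSpectrum,
                 error_cutoff: int | None = None) -> SpectrumFit:
    """Two-component constrained mixture fit plus genome-size estimate.

    Frequencies at or below the error cutoff (first local minimum of the
    histogram by default) are attributed to sequencing errors and
    excluded.  Both components share one dispersion; the second mean is
    fixed at twice the first.  An unconstrained two-mean refit is run as a
    diagnostic; when the fitted mixture collapses onto one component the
    ``single_component`` flag is raised and the genome size falls back to
    the dominant component's mean.
    """
    freqs_all, counts_all = spectrum.as_arrays()
    if freqs_all.size == 0:
        raise ValueError("empty spectrum")
    if error_cutoff is None:
        error_cutoff = first_local_minimum(freqs_all, counts_all)
    keep = freqs_all > error_cutoff
    freqs = freqs_all[keep].astype(np.float64)
    counts = counts_all[keep].astype(np.float64)
    if freqs.size < 3:
        raise ValueError("no usable histogram mass above the error cutoff")

    mode = float(freqs[np.argmax(counts)])
    mass = counts.sum()
    best = None
    for mu0 in (mode, mode / 2.0, mode * 0.75):
        x0 = [np.log(max(mu0, 1.0)), np.log(10.0), 0.0]
        res = optimize.minimize(
            _mixture_nll, x0, args=(freqs, counts, True), method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res
    mu = float(np.exp(best.x[0]))
    dispersion = float(np.clip(np.exp(np.clip(best.x[1], -50, 50)), 1e-2, 1e4))
    w = float(1.0 / (1.0 + np.exp(-best.x[2])))

    x0u = list(best.x) + [np.log(2 * mu)]
    res_u = optimize.minimize(
        _mixture_nll, x0u, args=(freqs, counts, False), method="Nelder-Mead",
        options={"maxiter": 6000, "xatol": 1e-6, "fatol": 1e-6},
    )
    mu_unc = (float(np.exp(res_u.x[0])), float(np.exp(res_u.x[3])))

    # single-component comparison: a unimodal (haploid-like) spectrum is
    # explained as well by one negative binomial; compare by BIC
    def single_nll(params):
        log_mu, log_r = np.clip(params, -30, 30)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = _nb_logpmf(freqs, np.exp(log_mu), np.exp(log_r))
        if not np.all(np.isfinite(ll)):
            return 1e18
        return -float(np.sum(counts * ll))

    res_s = optimize.minimize(
        single_nll, [np.log(mode), np.log(10.0)], method="Nelder-Mead",
        options={"maxiter": 3000, "xatol": 1e-6, "fatol": 1e-6},
    )
    n_obs = float(counts.sum())
    bic_mixture = 2 * best.fun + 3 * np.log(n_obs)
    bic_single = 2 * res_s.fun + 2 * np.log(n_obs)
    single = bool(bic_single <= bic_mixture) or min(w, 1 - w) < 0.05

    total_mass = float(np.sum(freqs * counts))
    if single:
        # one real peak: its mean is the effective depth
        mu_for_size = float(np.exp(res_s.x[0]))
        if min(w, 1 - w) < 0.05 and w < 0.5:
            mu_for_size = max(mu_for_size, 2 * mu)
    else:
        mu_for_size = mu
    genome_size = total_mass / mu_for_size
    return SpectrumFit(
        mu_het=mu,
        dispersion=dispersion,
        weight_single=w,
        fraction_single_copy=w,
        fraction_two_copy=1.0 - w,
        genome_size_estimate=genome_size,
        error_cutoff=int(error_cutoff),
        single_component=single,
        mu_unconstrained=mu_unc,
        log_likelihood=-float(best.fun),
    )
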