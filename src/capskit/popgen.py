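"""Biallelic population-survey statistics for genotyping assays.

Given per-population counts of the three genotypes at a biallelic locus
(RR resistant homozygotes, RS heterozygotes, SS susceptible homozygotes)
this module computes allele frequencies, observed and sample-size-corrected
expected heterozygosity, the within-population inbreeding coefficient
F_IS, and the exact Hardy-Weinberg probability test.

The exact test enumerates the full Levene conditional distribution: with
the allele counts nR and nS fixed, the probability of observing h
heterozygotes (h must share the parity of nR) is

    P(h) = N! / (n_RR! h! n_SS!) * 2^h * nR! nS! / (2N)!

and the p-value sums P over every configuration no more probable than the
observed one (ties included).  At biallelic scale full enumeration is
cheap, so no Monte Carlo chain is needed; log-factorials keep the
arithmetic overflow-free.

F_IS uses the single-population, sample-size-corrected estimator

    Ho = n_RS / N
    Hs = N/(N-1) * (1 - p^2 - q^2 - Ho/(2N))
    F_IS = 1 - Ho / Hs

(the within-population component of the Weir & Cockerham framework as
implemented by standard survey software); the naive 1 - Ho/(2pq) is also
exposed, clearly labelled, for comparison.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

_LOG2 = math.log(2.0)


class PopGenError(ValueError):
    """Invalid genotype counts or undefined statistic."""


class WahlundWarning(UserWarning):
    """Statistics computed on pooled samples from distinct populations."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Per-population genotype tallies at a biallelic locus."""

    population: str
    n_RR: int
    n_RS: int
    n_SS: int

    def __post_init__(self) -> None:
        for name in ("n_RR", "n_RS", "n_SS"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise PopGenError(f"{self.population}: {name} must be a non-negative integer")

    @property
    def N(self) -> int:
        return self.n_RR + self.n_RS + self.n_SS

    @property
    def n_R(self) -> int:
        return 2 * self.n_RR + self.n_RS

    @property
    def n_S(self) -> int:
        return 2 * self.n_SS + self.n_RS

    def swapped(self) -> "GenotypeCounts":
        """Relabel R<->S (frequency maps to its complement, F_IS is invariant)."""
        return GenotypeCounts(self.population, self.n_SS, self.n_RS, self.n_RR)


@dataclass(frozen=True)
class PopGenResult:
    """Summary statistics for one population."""

    population: str
    N: int
    fR: float
    Ho: float
    Hs: float | None
    Fis: float | None
    p_hwe: float


def allele_frequency(counts: GenotypeCounts) -> float:
    """Resistant-allele frequency fR = (2 n_RR + n_RS) / 2N."""
    if counts.N < 1:
        raise PopGenError(f"{counts.population}: no individuals")
    return counts.n_R / (2 * counts.N)


def fis_weir_cockerham(counts: GenotypeCounts) -> tuple[float, float | None, float | None]:
    """(Ho, Hs, Fis) with the sample-size-corrected estimator.

    A monomorphic sample has no defined inbreeding coefficient: Hs and
    Fis are returned as ``None``, never coerced to 0.
    """
    N = counts.N
    if N < 2:
        raise PopGenError(f"{counts.population}: N >= 2 required for Fis")
    Ho = counts.n_RS / N
    p = allele_frequency(counts)
    q = 1.0 - p
    if counts.n_R == 0 or counts.n_S == 0:
        return Ho, None, None
    Hs = (N / (N - 1)) * (1.0 - p * p - q * q - Ho / (2 * N))
    return Ho, Hs, 1.0 - Ho / Hs


def fis_naive(counts: GenotypeCounts) -> float | None:
    """Uncorrected 1 - Ho/(2pq); biased at small N, exposed for comparison."""
    p = allele_frequency(counts)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return None
    return 1.0 - (counts.n_RS / counts.N) / (2 * p * q)


def _log_levene(n_rr: int, h: int, n_ss: int) -> float:
    N = n_rr + h + n_ss
    nr = 2 * n_rr + h
    ns = 2 * n_ss + h
    return (
        math.lgamma(N + 1)
        - math.lgamma(n_rr + 1)
        - math.lgamma(h + 1)
        - math.lgamma(n_ss + 1)
        + h * _LOG2
        + math.lgamma(nr + 1)
        + math.lgamma(ns + 1)
        - math.lgamma(2 * N + 1)
    )


def levene_distribution(counts: GenotypeCounts) -> dict[int, float]:
    """Exact conditional probability of each heterozygote count h.

    Enumerates every genotype configuration compatible with the observed
    allele counts; the probabilities sum to 1.
    """
    nr, ns = counts.n_R, counts.n_S
    lo = nr % 2
    hi = min(nr, ns)
    return {
        h: math.exp(_log_levene((nr - h) // 2, h, (ns - h) // 2))
        for h in range(lo, hi + 1, 2)
    }


def hwe_exact_test(counts: GenotypeCounts) -> float:
    """Exact Hardy-Weinberg probability test (two-sided, ties included).

    Monomorphic samples return p = 1.  The p-value is the summed Levene
    probability of every configuration whose probability does not exceed
    the observed one (equal probabilities are included, the standard
    probability-test convention).
    """
    if counts.N < 1:
        raise PopGenError(f"{counts.population}: no individuals")
    if counts.n_R == 0 or counts.n_S == 0:
        return 1.0
    dist = levene_distribution(counts)
    p_obs = dist[counts.n_RS]
    # relative tolerance absorbs float noise in the tie comparison
    return min(1.0, sum(p for p in dist.values() if p <= p_obs * (1 + 1e-12)))


def population_summary(counts: GenotypeCounts) -> PopGenResult:
    Ho, Hs, Fis = fis_weir_cockerham(counts) if counts.N >= 2 else (counts.n_RS / counts.N, None, None)
    return PopGenResult(
        population=counts.population,
        N=counts.N,
        fR=allele_frequency(counts),
        Ho=Ho,
        Hs=Hs,
        Fis=Fis,
        p_hwe=hwe_exact_test(counts),
    )


def survey_table(
    populations: list[GenotypeCounts],
    pooled: bool = True,
    force_pooled_stats: bool = False,
) -> pd.DataFrame:
    """Survey report: genotype percentages, fR (%) and N per population.

    Rows RR/RS/SS carry genotype percentages to one decimal; fR is the
    resistant-allele frequency as a percentage; N the sample size.  The
    pooled column reports frequencies only — pooling distinct populations
    inflates homozygosity (Wahlund effect), so HWE and F_IS are not
    computed on the total unless ``force_pooled_stats`` is set, which
    emits an explicit warning.
    """
    if not populations:
        raise PopGenError("at least one population required")
    cols: dict[str, dict[str, float]] = {}

    def col(c: GenotypeCounts) -> dict[str, float]:
        N = c.N
        return {
            "RR": round(100 * c.n_RR / N, 1),
            "RS": round(100 * c.n_RS / N, 1),
            "SS": round(100 * c.n_SS / N, 1),
            "fR": round(100 * allele_frequency(c), 1),
            "N": N,
        }

    for c in populations:
        cols[c.population] = col(c)
    if pooled:
        total = GenotypeCounts(
            "Total",
            sum(c.n_RR for c in populations),
            sum(c.n_RS for c in populations),
            sum(c.n_SS for c in populations),
        )
        cols["Total"] = col(total)
        if force_pooled_stats:
            warnings.warn(
                "HWE/F_IS on pooled data: heterozygote deficit may be a Wahlund "
                "artefact of mixing differentiated populations",
                WahlundWarning,
                stacklevel=2,
            )
            _, _, fis = fis_weir_cockerham(total)
            cols["Total"]["Fis"] = float("nan") if fis is None else round(fis, 3)
            cols["Total"]["p_HWE"] = hwe_exact_test(total)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# I/O: counts CSV and GENEPOP export


def read_counts_csv(path: str | Path) -> list[GenotypeCounts]:
    """CSV columns: population,n_RR,n_RS,n_SS."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                GenotypeCounts(
                    row["population"], int(row["n_RR"]), int(row["n_RS"]), int(row["n_SS"])
                )
            )
    return out


def write_counts_csv(path: str | Path, populations: list[GenotypeCounts]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["population", "n_RR", "n_RS", "n_SS"])
        for c in populations:
            w.writerow([c.population, c.n_RR, c.n_RS, c.n_SS])


def write_genepop(
    path: str | Path,
    populations: list[GenotypeCounts],
    locus: str = "locus1",
    title: str = "capskit export",
) -> None:
    """Two-allele GENEPOP file (01 = R, 02 = S) for external cross-validation."""
    lines = [title, locus]
    for c in populations:
        lines.append("Pop")
        genos = ["0101"] * c.n_RR + ["0102"] * c.n_RS + ["0202"] * c.n_SS
        for i, g in enumerate(genos, 1):
            lines.append(f"{c.population}_{i} , {g}")
    Path(path).write_text("\n".join(lines) + "\n")


def counts_from_percentages(
    population: str, pct_rr: float, pct_rs: float, pct_ss: float, N: int
) -> GenotypeCounts:
    """Reconstruct integer counts from a printed percentage table.

    Nearest-integer of pct x N, with a consistency check that the counts
    recompute to the same percentages at one decimal.
    """
    c = GenotypeCounts(
        population,
        round(pct_rr * N / 100),
        round(pct_rs * N / 100),
        round(pct_ss * N / 100),
    )
    if c.N != N:
        raise PopGenError(f"{population}: reconstructed counts sum to {c.N}, expected {N}")
    for pct, n in ((pct_rr, c.n_RR), (pct_rs, c.n_RS), (pct_ss, c.n_SS)):
        if abs(round(100 * n / N, 1) - round(pct, 1)) > 0.05 + 1e-9:
            raise PopGenError(
                f"{population}: counts {c} do not recompute to {pct}% at 1 decimal"
            )
    return c
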