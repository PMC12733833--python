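"""Score observed gel lanes into SS/RS/RR genotype calls.

Band sizes read off a gel are length estimates, so matching uses a
relative tolerance (default 10% of the fragment length).  Bands the assay
itself flags as unresolvable (below ``min_visible_bp``) are dropped from
the expectation before matching — a 6 bp fragment is never demanded of a
2% agarose gel.  A lane is called only when exactly one genotype's band
set explains every observed band and leaves none of its own expected
bands unmatched; anything else is ambiguous.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .assay import AssayDesign, AssayError


@dataclass(frozen=True)
class ObservedLanes:
    """One gel lane: a sample's estimated band lengths for one assay."""

    sample_id: str
    bands: tuple[int, ...]
    assay_id: str = ""
    population: str = ""

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError(f"{self.sample_id}: empty band list")
        if any(b <= 0 for b in self.bands):
            raise ValueError(f"{self.sample_id}: band lengths must be positive")


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    call: str  # SS | RS | RR | ambiguous
    matched_bands: tuple[int, ...]
    unexplained_bands: tuple[int, ...]
    population: str = ""


def _match(observed: tuple[int, ...], expected: tuple[int, ...], tol: float) -> bool:
    def close(a: int, b: int) -> bool:
        return abs(a - b) <= tol * max(a, b)

    return all(any(close(o, e) for e in expected) for o in observed) and all(
        any(close(o, e) for o in observed) for e in expected
    )


def call_genotype(
    lanes: ObservedLanes, design: AssayDesign, tolerance_frac: float = 0.10
) -> GenotypeCall:
    """Match a lane against the assay's expected genotype band sets.

    Requires a discriminating design: a non-discriminating assay cannot be
    scored and the caller is directed to sequencing instead.
    """
    if not design.discriminates:
        raise AssayError(
            f"assay {design.enzyme.name}/{design.variant.label} does not discriminate "
            "the alleles; genotype by sequencing instead"
        )
    hits = [
        g
        for g, expected in design.genotype_patterns.items()
        if _match(lanes.bands, expected, tolerance_frac)
    ]
    if len(hits) == 1:
        g = hits[0]
        return GenotypeCall(lanes.sample_id, g, lanes.bands, (), lanes.population)
    return GenotypeCall(lanes.sample_id, "ambiguous", (), lanes.bands, lanes.population)


def tabulate_genotypes(calls: list[GenotypeCall]) -> "pd.DataFrame":
    """Aggregate calls into per-population RR/RS/SS counts.

    Ambiguous calls are tallied in their own column and excluded from N.
    """
    import pandas as pd

    pops: dict[str, dict[str, int]] = {}
    for c in calls:
        row = pops.setdefault(c.population or "all", {"RR": 0, "RS": 0, "SS": 0, "ambiguous": 0})
        row[c.call if c.call in row else "ambiguous"] += 1
    df = pd.DataFrame.from_dict(pops, orient="index").fillna(0).astype(int)
    if df.empty:
        return pd.DataFrame(columns=["RR", "RS", "SS", "ambiguous", "N"])
    df["N"] = df["RR"] + df["RS"] + df["SS"]
    import warnings

    for pop, row in df.iterrows():
        if row["N"] == 0:
            warnings.warn(f"population {pop!r}: all calls ambiguous, N = 0", stacklevel=2)
    return df


def to_genotype_counts(table: "pd.DataFrame") -> list:
    from .popgen import GenotypeCounts

    return [
        GenotypeCounts(str(pop), int(row["RR"]), int(row["RS"]), int(row["SS"]))
        for pop, row in table.iterrows()
    ]


def read_lanes_csv(path: str | Path) -> list[ObservedLanes]:
    """CSV columns: sample,population,assay,bands (semicolon-separated bp)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                ObservedLanes(
                    sample_id=row["sample"],
                    bands=tuple(int(b) for b in row["bands"].split(";") if b),
                    assay_id=row.get("assay", ""),
                    population=row.get("population", ""),
                )
            )
    return out


def write_calls_csv(path: str | Path, calls: list[GenotypeCall]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample", "population", "call", "matched_bands", "unexplained_bands"])
        for c in calls:
            w.writerow(
                [
                    c.sample_id,
                    c.population,
                    c.call,
                    ";".join(map(str, c.matched_bands)),
                    ";".join(map(str, c.unexplained_bands)),
                ]
            )
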