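"""Codon-bias statistics: GC profile, RSCU, and genome-wide ENc.

The effective number of codons (ENc, Wright's Nc) is computed once for an
entire count table -- the pooled coding sequences of a genome -- rather
than per gene, and stop codons participate as a synonymous family of their
own, like any amino acid.  Degeneracy classes are derived from the genetic
code in use, so organellar codes with different family structures are
handled uniformly, and the statistic can be evaluated under every
supported translation table when the true code of a genome is unknown.

Homozygosity estimation per family ``a`` with total count ``n_a`` and
within-family codon fractions ``p_i``::

    F_hat_a = (n_a * sum(p_i^2) - 1) / (n_a - 1)        (needs n_a >= 2)

Classes of equal degeneracy ``k`` are averaged (``F_bar_k``), and::

    Nc = m_1 + sum_k m_k / F_bar_k

with ``m_k`` the number of k-fold families.  Families with fewer than two
counted codons, or a non-positive ``F_hat``, are left out of their class
mean but still counted in ``m_k``; a class with no usable estimate is
repaired by linear interpolation over k between the nearest defined
classes (the k=1 class anchors the low end at F=1).  The estimator can
overshoot the number of codons in the partition at low bias; the result is
then clamped and flagged ``capped``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .counting import CodonCountTable
from .genetic_codes import (
    SUPPORTED_TABLE_IDS,
    DegeneracyFamilies,
    GeneticCode,
    canonical_codon_order,
    degeneracy_families,
    load_genetic_code,
)

__all__ = [
    "GcProfile",
    "FamilyHomozygosity",
    "EncResult",
    "InsufficientDataError",
    "gc_profile",
    "rscu",
    "family_homozygosities",
    "enc",
    "enc_all_codes",
]


class InsufficientDataError(ValueError):
    """No degeneracy class has a single usable homozygosity estimate."""


@dataclass(frozen=True)
class GcProfile:
    """Overall GC fraction and GC at each of the three codon positions.

    Computed from counted codons (post ambiguity-filtering), so the profile
    is always consistent with the codon frequency table it accompanies.
    ``gc_overall`` is exactly the mean of the three positional values.
    """

    gc_overall: float
    gc_pos: tuple[float, float, float]


def gc_profile(table: CodonCountTable) -> GcProfile:
    """GC content of a count table, overall and per codon position."""
    if table.n_codons == 0:
        raise ValueError("GC profile undefined for an empty count table")
    total = table.n_codons
    gc_at = [0, 0, 0]
    for codon, n in table.counts.items():
        if not n:
            continue
        for j in range(3):
            if codon[j] in "GC":
                gc_at[j] += n
    gc_pos = tuple(g / total for g in gc_at)
    return GcProfile(gc_overall=sum(gc_pos) / 3.0, gc_pos=gc_pos)  # type: ignore[arg-type]


def rscu(table: CodonCountTable, code: GeneticCode) -> np.ndarray:
    """Relative synonymous codon usage, in canonical codon order.

    For codon *i* in family *a* of degeneracy ``k_a``:
    ``RSCU_i = n_i * k_a / n_a`` -- the observed count over the count
    expected were the family used uniformly.  The stop family is included.
    Members of a family with ``n_a = 0`` get RSCU 0 (convention).
    """
    fams = degeneracy_families(code, include_stops=True)
    out = {c: 0.0 for c in canonical_codon_order()}
    for _, members in fams.families:
        n_a = sum(table.counts[c] for c in members)
        if n_a == 0:
            continue
        k = len(members)
        for c in members:
            out[c] = table.counts[c] * k / n_a
    return np.array([out[c] for c in canonical_codon_order()])


@dataclass(frozen=True)
class FamilyHomozygosity:
    """Wright's per-family homozygosity ingredients for one synonym family."""

    symbol: str
    degeneracy: int
    n_a: int
    p: tuple[float, ...]
    f_hat: float | None  # None when n_a < 2

    @property
    def usable(self) -> bool:
        """Contributes to its class mean: defined and strictly positive."""
        return self.f_hat is not None and self.f_hat > 0.0


def family_homozygosities(
    table: CodonCountTable, families: DegeneracyFamilies
) -> list[FamilyHomozygosity]:
    out: list[FamilyHomozygosity] = []
    for symbol, members in families.families:
        ordered = sorted(members)
        ns = [table.counts[c] for c in ordered]
        n_a = sum(ns)
        if n_a:
            p = tuple(n / n_a for n in ns)
        else:
            p = tuple(0.0 for _ in ordered)
        f_hat = None
        if n_a >= 2:
            f_hat = (n_a * sum(x * x for x in p) - 1.0) / (n_a - 1.0)
        out.append(
            FamilyHomozygosity(
                symbol=symbol,
                degeneracy=len(members),
                n_a=n_a,
                p=p,
                f_hat=f_hat,
            )
        )
    return out


@dataclass(frozen=True)
class EncResult:
    """One genome-wide ENc value and how it was obtained."""

    enc: float
    table_id: int
    include_stops: bool
    capped: bool
    #: degeneracy classes whose mean homozygosity had to be interpolated
    repaired_classes: tuple[int, ...] = ()


def _interpolate_missing(
    defined: dict[int, float], missing_k: int
) -> float:
    """Linear-in-k interpolation between the nearest defined classes.

    The one-fold class anchors the low end (F=1 by definition); a missing
    class beyond the last defined one takes the nearest defined value.
    """
    anchors = dict(defined)
    anchors.setdefault(1, 1.0)
    lower = [k for k in anchors if k < missing_k]
    upper = [k for k in anchors if k > missing_k]
    if lower and upper:
        k_lo, k_hi = max(lower), min(upper)
        t = (missing_k - k_lo) / (k_hi - k_lo)
        return anchors[k_lo] + t * (anchors[k_hi] - anchors[k_lo])
    if lower:
        return anchors[max(lower)]
    return anchors[min(upper)]


def enc(
    table: CodonCountTable,
    code: GeneticCode,
    include_stops: bool = True,
) -> EncResult:
    """Genome-wide effective number of codons under one genetic code.

    Ranges from the number of synonym families (one codon used per family,
    maximal bias) up to the number of codons in the partition (uniform
    usage; 64 for the standard code with stops, 61 without).

    Raises
    ------
    ValueError
        For an empty table.
    InsufficientDataError
        When every multi-codon family has fewer than two counted codons,
        so no homozygosity is estimable at all.
    """
    if table.n_codons == 0:
        raise ValueError("ENc undefined for an empty count table")
    families = degeneracy_families(code, include_stops=include_stops)
    homs = family_homozygosities(table, families)

    m_k: dict[int, int] = families.class_sizes()
    by_class: dict[int, list[float]] = {}
    for h in homs:
        if h.degeneracy >= 2 and h.usable:
            by_class.setdefault(h.degeneracy, []).append(h.f_hat)  # type: ignore[arg-type]
    if not by_class and any(k >= 2 for k in m_k):
        raise InsufficientDataError(
            "no synonymous family has >= 2 counted codons; ENc inestimable"
        )
    f_bar: dict[int, float] = {k: float(np.mean(v)) for k, v in by_class.items()}
    repaired: list[int] = []
    for k in sorted(m_k):
        if k >= 2 and k not in f_bar:
            f_bar[k] = _interpolate_missing(dict(f_bar), k)
            repaired.append(k)

    nc = float(m_k.get(1, 0))
    for k, count in m_k.items():
        if k >= 2:
            nc += count / f_bar[k]

    cap = float(sum(len(members) for _, members in families.families))
    capped = nc > cap
    return EncResult(
        enc=min(nc, cap),
        table_id=code.table_id,
        include_stops=include_stops,
        capped=capped,
        repaired_classes=tuple(repaired),
    )


def enc_all_codes(
    table: CodonCountTable,
    include_stops: bool = True,
) -> tuple[dict[int, EncResult], dict[int, str]]:
    """Evaluate ENc under every supported translation table.

    Sequence archives do not always record a genome's genetic code, so the
    statistic is offered under all codes and the user picks the applicable
    one.  Returns ``(results, failures)``; a code that fails (e.g. too
    little data for its family structure) is absent from ``results`` and
    explained in ``failures`` -- never a global error.
    """
    results: dict[int, EncResult] = {}
    failures: dict[int, str] = {}
    for table_id in SUPPORTED_TABLE_IDS:
        try:
            results[table_id] = enc(
                table, load_genetic_code(table_id), include_stops=include_stops
            )
        except ValueError as exc:
            failures[table_id] = str(exc)
    return results, failures
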