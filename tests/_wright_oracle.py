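"""Independent, literal transcription of Wright's ENc estimator.

Used only as a test oracle.  Families are derived straight from
Biopython's NCBI table data, and the estimator follows the published
formulation step by step, with the same repair rules as the library:
per-family homozygosity F = (n * sum(p_i^2) - 1) / (n - 1) for n >= 2,
class means over usable (positive) F values, a missing class interpolated
linearly in k between the nearest defined classes (k=1 anchored at F=1),
and the result capped at the number of codons partitioned.
"""

from __future__ import annotations

from itertools import product

from Bio.Data import CodonTable


def families(table_id: int, include_stops: bool) -> list[list[str]]:
    bio = CodonTable.unambiguous_dna_by_id[table_id]
    groups: dict[str, list[str]] = {}
    for codon in ("".join(p) for p in product("TCAG", repeat=3)):
        if codon in bio.stop_codons:
            if include_stops:
                groups.setdefault("*", []).append(codon)
        else:
            groups.setdefault(bio.forward_table[codon], []).append(codon)
    return list(groups.values())


def wright_enc(
    counts: dict[str, int], table_id: int = 1, include_stops: bool = True
) -> float:
    fams = families(table_id, include_stops)
    m: dict[int, int] = {}
    f_by_class: dict[int, list[float]] = {}
    for fam in fams:
        k = len(fam)
        m[k] = m.get(k, 0) + 1
        n = sum(counts.get(c, 0) for c in fam)
        if n >= 2:
            s = sum((counts.get(c, 0) / n) ** 2 for c in fam)
            f = (n * s - 1.0) / (n - 1.0)
            if f > 0.0:
                f_by_class.setdefault(k, []).append(f)
    if not f_by_class and any(k >= 2 for k in m):
        raise ValueError("insufficient data for Wright's estimator")
    f_bar = {k: sum(v) / len(v) for k, v in f_by_class.items()}
    for k in sorted(m):
        if k >= 2 and k not in f_bar:
            anchors = dict(f_bar)
            anchors.setdefault(1, 1.0)
            lower = [x for x in anchors if x < k]
            upper = [x for x in anchors if x > k]
            if lower and upper:
                lo, hi = max(lower), min(upper)
                f_bar[k] = anchors[lo] + (k - lo) / (hi - lo) * (
                    anchors[hi] - anchors[lo]
                )
            elif lower:
                f_bar[k] = anchors[max(lower)]
            else:
                f_bar[k] = anchors[min(upper)]
    nc = float(m.get(1, 0))
    for k, count in m.items():
        if k >= 2:
            nc += count / f_bar[k]
    cap = float(sum(len(f) for f in fams))
    return min(nc, cap)
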