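"""Literal, loop-based reference implementations used as test oracles.

Everything here recomputes the pipeline's statistics cell by cell with
exact rational arithmetic and no vectorization, staying independent of the
package's implementation paths.
"""

from __future__ import annotations

import math
from fractions import Fraction


def oracle_calls(scores: list[list[float | None]], cutoff: float):
    """Per-(line, gene) call: True/False/None, essential iff score < cutoff."""
    out = []
    for row in scores:
        out_row = []
        for v in row:
            if v is None or (isinstance(v, float) and math.isnan(v)):
                out_row.append(None)
            else:
                out_row.append(v < cutoff)
        out.append(out_row)
    return out


def oracle_gene_stats(calls, gene_index: int):
    """(frequency Fraction, n_evaluable, n_essential) for one gene column."""
    n_eval = n_ess = 0
    for row in calls:
        c = row[gene_index]
        if c is None:
            continue
        n_eval += 1
        if c:
            n_ess += 1
    if n_eval == 0:
        return None
    return Fraction(n_ess, n_eval), n_eval, n_ess


def oracle_category(freq: Fraction, aeg=Fraction(9, 10), reg=Fraction(1, 10)):
    if freq > aeg:
        return "always_essential"
    if freq < reg:
        return "rarely_essential"
    return "partially_essential"


def oracle_classify(scores, symbols, cutoff=-1.0):
    """symbol -> (freq, n_eval, n_ess, category); all-missing genes omitted."""
    calls = oracle_calls(scores, cutoff)
    result = {}
    for j, sym in enumerate(symbols):
        stats = oracle_gene_stats(calls, j)
        if stats is None:
            continue
        freq, n_eval, n_ess = stats
        result[sym] = (freq, n_eval, n_ess, oracle_category(freq))
    return result


def oracle_pathway_summary(classified: dict, pathways: dict):
    """pathway -> dict of counts, recomputed by explicit membership loops."""
    out = {}
    for name, members in pathways.items():
        seen = list(dict.fromkeys(members))
        present = [g for g in seen if g in classified]
        missing = [g for g in seen if g not in classified]
        counts = {"always_essential": 0, "partially_essential": 0,
                  "rarely_essential": 0}
        for g in present:
            counts[classified[g][3]] += 1
        out[name] = {
            "n_annotated": len(seen),
            "n_present": len(present),
            "n_aeg": counts["always_essential"],
            "n_peg": counts["partially_essential"],
            "n_reg": counts["rarely_essential"],
            "missing_genes": missing,
        }
    return out


def oracle_fractions(scores, symbols, pathways, cutoff=-1.0):
    """(line index, pathway) -> Fraction: AEG/PEG essential members / present."""
    calls = oracle_calls(scores, cutoff)
    classified = oracle_classify(scores, symbols, cutoff)
    col_of = {s: j for j, s in enumerate(symbols)}
    out = {}
    for name, members in pathways.items():
        seen = list(dict.fromkeys(members))
        present = [g for g in seen if g in classified]
        if not present:
            continue
        for i in range(len(scores)):
            numer = 0
            for g in present:
                cat = classified[g][3]
                if cat in ("always_essential", "partially_essential"):
                    c = calls[i][col_of[g]]
                    if c is True:  # missing counts as non-essential
                        numer += 1
            out[(i, name)] = Fraction(numer, len(present))
    return out


def oracle_best_split(values):
    """Exhaustive-split Otsu: (best threshold, between/total ratio)."""
    x = sorted(values)
    n = len(x)
    mean = sum(x) / n
    total = sum((v - mean) ** 2 for v in x) / n
    if n < 2 or total == 0:
        return None, 0.0
    best_score, best_thr = -1.0, None
    for k in range(1, n):
        if x[k] <= x[k - 1]:
            continue
        lo, hi = x[:k], x[k:]
        mu0 = sum(lo) / k
        mu1 = sum(hi) / (n - k)
        between = (k / n) * ((n - k) / n) * (mu0 - mu1) ** 2
        if between > best_score:
            best_score = between
            best_thr = (x[k - 1] + x[k]) / 2
    if best_thr is None:
        return None, 0.0
    return best_thr, best_score / total
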