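"""Recovery metrics against the synthetic truth ledger.

These helpers score pipeline output against the planted signal of a
synthetic atlas: recall (fraction of planted genes recovered) and
false-discovery proportion (fraction of calls not backed by planted
signal).

One accounting subtlety: a planted species-DEG gene carries its species
effect in a designated tissue, which makes it *genuinely* over-expressed
in that tissue relative to the rest — in species A it satisfies the
tissue-specific-gene definition by construction.  Such calls are planted
signal of a different kind, not false discoveries, so TSG scoring treats
them as neither hits nor false positives.  Recall is always measured
against the planted TSG sets alone.
"""

from __future__ import annotations

from typing import Mapping

from .de import DEResult
from .synthetic import SyntheticTruth

__all__ = ["tsg_recovery", "deg_recovery", "hkg_recovery"]


def _set_recovery(
    called: Mapping[str, set],
    planted: Mapping[str, frozenset],
    exempt: Mapping[str, frozenset] | None = None,
) -> tuple[int, int, int]:
    """(true positives, false positives, planted total) over tissues."""
    exempt = exempt or {}
    tp = fp = total = 0
    for tissue, truth_set in planted.items():
        total += len(truth_set)
        tp += len(called.get(tissue, set()) & truth_set)
    for tissue, call_set in called.items():
        allowed = set(planted.get(tissue, frozenset())) | set(
            exempt.get(tissue, frozenset())
        )
        fp += len(call_set - allowed)
    return tp, fp, total


def tsg_recovery(
    truth: SyntheticTruth,
    called_a: Mapping[str, set],
    called_b: Mapping[str, set],
) -> dict:
    """Recall and false-discovery proportion of TSG calls, both species pooled.

    Species-A calls of planted DEG genes in their designated tissues are
    exempt from the false-positive count (see module docstring).
    """
    tp_a, fp_a, tot_a = _set_recovery(called_a, truth.tsg_a, exempt=truth.deg_a)
    tp_b, fp_b, tot_b = _set_recovery(called_b, truth.tsg_b)
    tp, fp, total = tp_a + tp_b, fp_a + fp_b, tot_a + tot_b
    n_called = fp + tp
    return {
        "recall": tp / total if total else float("nan"),
        "fdp": fp / n_called if n_called else 0.0,
        "n_planted": total,
        "n_called_scored": n_called,
    }


def deg_recovery(truth: SyntheticTruth, deg_results: Mapping[str, DEResult]) -> dict:
    """Recall and false-discovery proportion of cross-species DEG calls.

    Planted DEGs are up-regulated in species A; a hit requires the call in
    the planted tissue with the correct (up) direction.  Any significant
    call not planted in its tissue is a false positive.  Gene ids in the
    result tables are species-A ids, matching ``truth.deg_a``.
    """
    called_up = {t: res.called("up") for t, res in deg_results.items()}
    called_any = {t: res.called("deg") for t, res in deg_results.items()}
    tp, _, total = _set_recovery(called_up, truth.deg_a)
    _, fp, _ = _set_recovery(called_any, truth.deg_a)
    n_called = sum(len(s) for s in called_any.values())
    return {
        "recall": tp / total if total else float("nan"),
        "fdp": fp / n_called if n_called else 0.0,
        "n_planted": total,
        "n_called": n_called,
    }


def hkg_recovery(truth: SyntheticTruth, records_a, records_b=None) -> dict:
    """Fraction of planted housekeeping genes tiered as low-variability.

    ``records_a`` (and optionally ``records_b``) are per-species record
    tables from :func:`atlascmp.housekeeping.hkg_records`, keyed by that
    species' gene ids.
    """
    n = hits = 0
    for records, planted in ((records_a, truth.hkg_a), (records_b, truth.hkg_b)):
        if records is None:
            continue
        present = [g for g in planted if g in records.index]
        n += len(present)
        hits += int((records.loc[present, "variability_tier"] == "low").sum())
    return {
        "low_tier_rate": hits / n if n else float("nan"),
        "n_planted_scored": n,
    }
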