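"""Product-limit (Kaplan–Meier) estimation with delayed entry.

With left truncation the risk set at time t is {i : entry_i < t <= exit_i},
so the number at risk can rise and fall as subjects enter at staggered ages.
The curves answer "what fraction of at-risk persons is still undiagnosed at
age t", e.g. stratified by allele count.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .phenotype import SurvivalPhenotype

__all__ = ["km_delayed_entry", "km_curve"]


def km_curve(pheno: SurvivalPhenotype) -> pd.DataFrame:
    """Single delayed-entry product-limit curve.

    Returns a frame with one row per distinct event time: ``time``,
    ``n_risk`` (subjects with entry < time <= exit), ``n_event`` and the
    ``survival`` estimate ``prod(1 - d/n)``.
    """
    event_times = np.unique(pheno.exit[pheno.status == 1])
    if len(event_times) == 0:
        return pd.DataFrame(
            {"time": [], "n_risk": [], "n_event": [], "survival": []}
        ).astype({"time": float, "n_risk": int, "n_event": int, "survival": float})
    exit_sorted = np.sort(pheno.exit)
    entry_sorted = np.sort(pheno.entry)
    n = len(pheno)
    # at risk: exit >= t minus entry >= t
    n_ge_exit = n - np.searchsorted(exit_sorted, event_times, side="left")
    n_ge_entry = n - np.searchsorted(entry_sorted, event_times, side="left")
    n_risk = n_ge_exit - n_ge_entry
    ev_sorted = np.sort(pheno.exit[pheno.status == 1])
    n_event = (
        np.searchsorted(ev_sorted, event_times, side="right")
        - np.searchsorted(ev_sorted, event_times, side="left")
    )
    survival = np.cumprod(1.0 - n_event / n_risk)
    return pd.DataFrame(
        {"time": event_times, "n_risk": n_risk, "n_event": n_event, "survival": survival}
    )


def km_delayed_entry(pheno: SurvivalPhenotype, group=None) -> dict:
    """Delayed-entry Kaplan–Meier curves, one per group level.

    ``group`` is a per-individual label (e.g. allele count 0/1/2); ``None``
    yields a single curve keyed ``"all"``. Declared levels with zero
    individuals (categorical inputs) are omitted with a warning.
    """
    if group is None:
        return {"all": km_curve(pheno)}
    declared = None
    if isinstance(group, pd.Categorical) or isinstance(
        getattr(group, "dtype", None), pd.CategoricalDtype
    ):
        declared = list(pd.Categorical(group).categories)
    group = np.asarray(group)
    if len(group) != len(pheno):
        raise ValueError("group labels must cover all individuals")
    curves = {}
    for level in pd.unique(group):
        curves[level] = km_curve(pheno.subset(group == level))
    if declared is not None:
        for level in declared:
            if level not in curves:
                warnings.warn(f"group level {level!r} has zero individuals; omitted")
    return curves


def km_to_tsv(curves: dict, path) -> None:
    """Write curves as TSV: group, time, n_risk, n_event, survival."""
    frames = []
    for level, df in curves.items():
        out = df.copy()
        out.insert(0, "group", level)
        frames.append(out)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
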