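"""Functional distances from mixed continuous/binary trait tables.

Gower's coefficient with range normalization for continuous traits and
simple matching for binary ones, pairwise-complete over missing values.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import DataValidationError, DistanceMatrix, TraitTable


def functional_distance(
    traits: TraitTable, trait_subset: Iterable[str] | None = None
) -> DistanceMatrix:
    """Gower distance over the selected traits, in [0, 1].

    Continuous traits contribute |x_i - x_j| / range(trait); binary traits
    contribute 0/1 mismatch. Per pair, contributions are averaged over the
    traits observed in both species (pairwise-complete). Species with no
    usable selected trait are dropped with a warning; constant continuous
    traits (zero range) carry no information and are skipped.
    """
    names = list(trait_subset) if trait_subset is not None else traits.trait_names
    if not names:
        raise DataValidationError("no traits selected")
    missing = [t for t in names if t not in traits.trait_names]
    if missing:
        raise DataValidationError(f"unknown traits: {missing}")

    vals = traits.values[names]
    usable = vals.notna().any(axis=1)
    dropped = list(vals.index[~usable])
    if dropped:
        warnings.warn(
            f"species with all-missing selected traits excluded from "
            f"functional distances: {dropped}",
            stacklevel=2,
        )
    vals = vals.loc[usable]
    if vals.shape[0] < 2:
        raise DataValidationError("fewer than 2 species with usable trait values")

    species = list(vals.index)
    n = len(species)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for t in names:
        x = vals[t].to_numpy(dtype=float)
        obs = ~np.isnan(x)
        both = np.outer(obs, obs)
        if traits.trait_kind[t] == "continuous":
            rng = np.nanmax(x) - np.nanmin(x)
            if rng == 0 or np.isnan(rng):
                continue  # constant trait: no contribution
            diff = np.abs(np.subtract.outer(x, x)) / rng
        else:
            diff = (np.not_equal.outer(x, x)).astype(float)
        diff = np.where(both, diff, 0.0)
        num += np.where(both, diff, 0.0)
        den += both.astype(float)
    with np.errstate(invalid="ignore"):
        d = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    if np.isnan(d[~np.eye(n, dtype=bool)]).any():
        bad = [
            (species[i], species[j])
            for i in range(n)
            for j in range(i + 1, n)
            if np.isnan(d[i, j])
        ]
        raise DataValidationError(f"species pairs with no shared observed trait: {bad[:5]}")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(
        values=pd.DataFrame(d, index=species, columns=species), kind="functional"
    )
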