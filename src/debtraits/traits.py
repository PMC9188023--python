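"""Per-species trait tables derived from DEB parameter records.

The comparison unit of the package: one row per species holding the
derived life-history traits at the reference temperature (20 degC) and
abundant food, plus auxiliaries and failure flags.  The twelve traits
used for trait-space embedding are listed in :data:`MDS_TRAITS`.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .deb_core import (
    DEFAULT_CHEM,
    ChemicalConstants,
    DEBParameters,
    NonViableError,
    at_temperature,
    compound_parameters,
    life_history,
)

__all__ = [
    "MDS_TRAITS",
    "TRAIT_COLUMNS",
    "build_trait_table",
    "lifetime_neonate_mass",
]

#: The twelve traits entering the trait-space (MDS) comparison: ages at
#: birth/puberty, life span, ultimate weight, reproduction rate, egg cost,
#: reserve capacity, three primary rate parameters, supply stress and
#: precociality.
MDS_TRAITS = [
    "a_b", "a_p", "a_m", "Ww_i", "R_i", "E_0",
    "E_m", "v", "p_M", "p_Am", "s_s", "s_Hbp",
]

#: Full column order of a trait table.
TRAIT_COLUMNS = [
    "species_id", "taxon", "sub_taxon",
    "a_b", "a_p", "a_m", "Ww_i", "R_i", "E_0",
    "E_m", "v", "p_M", "p_Am", "s_s", "s_Hbp",
    "Ww_b", "Ww_p", "L_b", "L_p", "L_i",
    "r_B", "r_max", "jO2_spec", "N_mass_life",
    "non_viable", "stalled", "demand_bound",
]


def build_trait_table(
    params: Iterable[DEBParameters],
    c: ChemicalConstants = DEFAULT_CHEM,
    f: float = 1.0,
    T: float | None = None,
    neonate_mass_window: str = "post-puberty",
) -> pd.DataFrame:
    """Derive the full trait table for a collection of species.

    Each row is computed by the single-species operations of
    :mod:`debtraits.deb_core` (embryo shooting, puberty integration, aging
    integral, closed-form traits).  Species that fail (non-viable embryo,
    stalled maturation, demand-bound reproduction) are retained with their
    failure flag set and the affected traits missing, never dropped, so
    downstream survivor curves can state their denominator.

    Parameters
    ----------
    params
        Parameter records; ``species_id`` must be unique.
    c
        Chemical conversion constants.
    f
        Scaled functional response; records carrying their own ``f`` keep it.
    T
        Optional body temperature (K).  If given, all rates are
        Arrhenius-corrected from the reference temperature before traits
        are derived; by default traits are reported at 20 degC.
    neonate_mass_window
        Reproduction window convention for lifetime neonate mass:
        ``"post-puberty"`` (R_i * (a_m - a_p) * Ww_b, default) or
        ``"lifespan"`` (R_i * a_m * Ww_b).
    """
    params = list(params)
    ids = [p.species_id for p in params]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate species_id: {', '.join(dupes)}")

    rows = []
    for p in params:
        if T is not None:
            p_run = at_temperature(p, T, c.T_ref)
        else:
            p_run = p
        f_run = p.f if p.f != 1.0 and f == 1.0 else f
        cp = compound_parameters(p_run, c)
        row: dict = {
            "species_id": p.species_id,
            "taxon": p.taxon,
            "sub_taxon": p.sub_taxon,
            "E_m": cp.E_m,
            "v": p_run.v,
            "p_M": p_run.p_M,
            "p_Am": p_run.p_Am,
            "non_viable": False,
            "stalled": False,
            "demand_bound": False,
        }
        try:
            lh = life_history(p_run, c, f_run)
        except NonViableError:
            row["non_viable"] = True
            rows.append(row)
            continue
        row.update(
            a_b=lh.a_b, a_p=lh.a_p, a_m=lh.a_m,
            Ww_i=lh.Ww_i, R_i=lh.R_i, E_0=lh.E_0,
            s_s=lh.s_s, s_Hbp=lh.s_Hbp,
            Ww_b=lh.Ww_b, Ww_p=lh.Ww_p,
            L_b=lh.L_b, L_p=lh.L_p, L_i=lh.L_i,
            r_B=lh.r_B, r_max=lh.r_max, jO2_spec=lh.jO2_spec,
            stalled=lh.stalled, demand_bound=lh.demand_bound,
        )
        rows.append(row)

    table = pd.DataFrame(rows).reindex(columns=TRAIT_COLUMNS)
    table["N_mass_life"] = lifetime_neonate_mass(table, window=neonate_mass_window)
    for flag in ("non_viable", "stalled", "demand_bound"):
        table[flag] = table[flag].astype(bool)
    return table


def lifetime_neonate_mass(
    table: pd.DataFrame, window: str = "post-puberty"
) -> pd.Series:
    """Lifetime cumulated neonate mass production (g) per species.

    The continuous reproduction rate at ultimate size, integrated over the
    reproductive window and converted to mass via neonate wet weight:
    ``R_i * (a_m - a_p) * Ww_b`` by default.  Reproduction starts at
    puberty, hence the default window; ``window="lifespan"`` uses ``a_m``
    alone.  Rows with missing inputs yield missing output.
    """
    if window == "post-puberty":
        span = table["a_m"] - table["a_p"]
    elif window == "lifespan":
        span = table["a_m"]
    else:
        raise ValueError(f"unknown window {window!r}")
    return (table["R_i"] * span * table["Ww_b"]).astype(float)
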