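"""Results layer: kerma conversion, contribution fractions, occupancy
weighting and isodose smallest-area sets.

A contribution matrix (region x observation point air kerma per unit areal
activity, from either transport engine) is reduced to per-observation-point
dose-contribution fractions — each source region's kerma divided by the
summed kerma from all regions at that point — then optionally collapsed to
house-level fractions with a residential occupancy profile (hours per room
per day), and to isodose sets: the smallest ground area contributing a
given percentage of the total dose at one observation point.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from suburbdose.materials import Material

__all__ = [
    "KermaCoefficients",
    "fluence_to_kerma",
    "contribution_fractions",
    "fraction_table",
    "occupancy_weighted",
    "isodose_set",
    "summarize_scenario",
    "headline_statistics",
    "top_cross_property",
]

# Gy per (MeV * cm^2/g): 1.602e-13 J/MeV times 10^3 g/kg
GY_PER_MEV_CM2_G = 1.602176634e-10
INDOOR_OPS = [f"OP{i}" for i in range(1, 12)]
OUTDOOR_OP = "OP_OUT"


class KermaCoefficients:
    """Air-kerma-per-fluence k(E) in Gy cm^2 per photon, from an air material."""

    def __init__(self, air: Material) -> None:
        self._air = air

    def __call__(self, energy_mev) -> np.ndarray | float:
        muen = self._air.table.mass_energy_absorption(energy_mev)
        return np.asarray(energy_mev, dtype=float) * GY_PER_MEV_CM2_G * muen


def fluence_to_kerma(spectrum, air: Material) -> float:
    """Fold a fluence spectrum into air kerma free-in-air (Gy).

    ``spectrum`` is a TallySpectrum (or anything with bin_edges/fluence);
    each bin is evaluated at its geometric-midpoint energy."""
    fl = np.asarray(spectrum.fluence, dtype=float)
    if fl.size == 0 or fl.sum() == 0:
        return 0.0
    edges = np.asarray(spectrum.bin_edges, dtype=float)
    mids = np.sqrt(edges[:-1] * edges[1:])
    k = KermaCoefficients(air)(mids)
    return float(np.sum(fl * k))


def _matrix_pivot(matrix: pd.DataFrame, value="kerma") -> pd.DataFrame:
    return matrix.pivot_table(index="op", columns="region", values=value,
                              aggfunc="sum")


def contribution_fractions(matrix: pd.DataFrame, op: str) -> pd.DataFrame:
    """Fractions of total kerma at one observation point, by source region.

    Returns a DataFrame indexed by region with columns (fraction, rel_err);
    the relative error combines the component errors in the uncorrelated
    approximation."""
    rows = matrix[matrix["op"] == op]
    if rows.empty:
        raise KeyError(f"observation point {op!r} not in matrix")
    kerma = rows.set_index("region")["kerma"]
    total = kerma.sum()
    if total <= 0:
        raise ValueError(f"all-zero kerma row at {op}: fractions undefined")
    frac = kerma / total
    re = rows.set_index("region")["rel_err"]
    abs_err = (kerma * re) ** 2
    tot_err = abs_err.sum()
    # var(f_i) ~ f_i^2 [ (1-2 f_i) re_i^2 + sum_j f_j^2 re_j^2 / f_i^2 ... ]
    # use the simple uncorrelated ratio form: re_f^2 = re_i^2 + re_tot^2
    re_tot = math.sqrt(tot_err) / total if total > 0 else 0.0
    frac_re = np.sqrt(re**2 + re_tot**2)
    return pd.DataFrame({"fraction": frac, "rel_err": frac_re})


def fraction_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """All observation points at once: rows OPs, columns regions, values
    fractions summing to 1 per row."""
    piv = _matrix_pivot(matrix)
    totals = piv.sum(axis=1)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"all-zero kerma rows at {bad}: fractions undefined")
    return piv.div(totals, axis=0)


def occupancy_weighted(
    fractions: pd.DataFrame, occupancy_hours: dict[str, float]
) -> pd.Series:
    """House-level region fractions from per-room fractions.

    ``fractions`` has room/OP labels as index (rows summing to 1);
    ``occupancy_hours`` maps room label -> hours per day.  The result is the
    convex combination with weights hours/total-hours, so regions' house
    fractions again sum to 1.
    """
    total = sum(occupancy_hours.values())
    if total <= 0:
        raise ValueError("occupancy profile has zero total hours")
    missing = [r for r in occupancy_hours if r not in fractions.index]
    if missing:
        raise KeyError(f"rooms {missing} missing from the fraction table")
    out = None
    for room, hours in occupancy_hours.items():
        term = fractions.loc[room] * (hours / total)
        out = term if out is None else out + term
    return out


def isodose_set(grid: pd.DataFrame, p: float) -> tuple[pd.DataFrame, float]:
    """Smallest-area cell set contributing at least p% of the total dose.

    Cells are ranked by contribution (descending) and accumulated greedily
    until the cumulative contribution reaches p% of the grid total.  Ties
    are broken by distance to the observation point (nearer first), then by
    cell index.  Returns (selected cells, their total area in m^2)."""
    if not 0 < p <= 100:
        raise ValueError(f"p must be in (0, 100], got {p}")
    total = grid["kerma"].sum()
    if total <= 0:
        raise ValueError("grid total dose is zero")
    if "distance_m" in grid.columns:
        dist = grid["distance_m"].to_numpy()
    else:
        cx, cy, cz = grid.attrs.get("op_center", (0.0, 0.0, 1.0))
        dist = np.hypot(grid["x"] - cx, grid["y"] - cy)
    order = np.lexsort((np.arange(len(grid)), dist, -grid["kerma"].to_numpy()))
    kerma_sorted = grid["kerma"].to_numpy()[order]
    cum = np.cumsum(kerma_sorted)
    target = p / 100.0 * total
    # number of cells needed so that cum >= target (within float tolerance)
    n_sel = int(np.searchsorted(cum, target * (1.0 - 1e-12)) + 1)
    n_sel = min(n_sel, int((kerma_sorted > 0).sum()))
    chosen = grid.iloc[order[:n_sel]]
    return chosen, float(chosen["area_m2"].sum())


# --------------------------------------------------------------------------
# scenario-level reports


def _split_op(op_label: str) -> tuple[str, str]:
    prop, _, room = op_label.partition(":")
    return prop, room


def summarize_scenario(
    matrix: pd.DataFrame, occupancy_hours: dict[str, float]
) -> dict[str, pd.DataFrame]:
    """Standard report tables from one flavour's contribution matrix.

    Returns a dict with:
      * ``per_op``        — fractions per (property, OP) x region;
      * ``per_property``  — indoor-average (unweighted over OP1-OP11) and
        outdoor fractions per property x region;
      * ``occupancy``     — occupancy-weighted house-level fractions;
      * ``cross_property``— contributions at single indoor OPs from other
        properties' gardens, ranked (top 10);
      * ``flagged``       — any (region, op) pairs carrying a statistical
        warning flag, empty for deterministic engines.
    """
    frac = fraction_table(matrix)
    frac.index = pd.MultiIndex.from_tuples(
        [_split_op(op) for op in frac.index], names=["property", "room"]
    )
    per_op = frac.sort_index()

    rows_avg = []
    for prop in sorted({p for p, _ in per_op.index}):
        sub = per_op.loc[prop]
        indoor = sub.loc[[r for r in INDOOR_OPS if r in sub.index]]
        rows_avg.append(
            pd.concat(
                {
                    (prop, "indoor_average"): indoor.mean(axis=0),
                    (prop, "outdoor"): sub.loc[OUTDOOR_OP]
                    if OUTDOOR_OP in sub.index
                    else pd.Series(np.nan, index=sub.columns),
                },
                axis=1,
            ).T
        )
    per_property = pd.concat(rows_avg)
    per_property.index.names = ["property", "location"]

    occ_rows = {}
    for prop in sorted({p for p, _ in per_op.index}):
        sub = per_op.loc[prop]
        occ_rows[prop] = occupancy_weighted(sub, occupancy_hours)
    occupancy = pd.DataFrame(occ_rows).T
    occupancy.index.name = "property"

    cross = []
    for (prop, room), row in per_op.iterrows():
        if room not in INDOOR_OPS:
            continue
        for region, f in row.items():
            if region.startswith("P") and region != prop:
                cross.append((region, prop, room, round(100.0 * f, 2)))
    cross_df = (
        pd.DataFrame(cross,
                     columns=["source_property", "property", "room",
                              "contribution_pct"])
        .sort_values("contribution_pct", ascending=False)
        .head(10)
        .reset_index(drop=True)
    )

    flagged = (
        matrix[matrix["flagged"]]
        if "flagged" in matrix.columns
        else matrix.iloc[0:0]
    )
    return {
        "per_op": per_op,
        "per_property": per_property,
        "occupancy": occupancy,
        "cross_property": cross_df,
        "flagged": flagged,
    }


def headline_statistics(
    matrices: dict[str, pd.DataFrame],
    properties: tuple[str, ...] = ("P12", "P13", "P14", "P15"),
    averaged_properties: tuple[str, ...] = ("P12", "P13", "P15"),
) -> dict:
    """Neighbourhood-level summary statistics over both house flavours.

    ``matrices`` maps flavour ("brick"/"wood") to a contribution matrix.
    Percentages throughout:

    * ``own_indoor_avg_pct[flavour]`` — mean over the 11 indoor OPs and the
      ``averaged_properties`` of the own-garden fraction (the central-lot
      house is excluded from the average, as its own-garden share behaves
      differently);
    * ``own_indoor_by_property`` / ``own_outdoor_by_property``;
    * ``street_max_indoor_pct`` — max street fraction at any indoor OP of
      any instrumented property, either flavour;
    * ``other_min_indoor_pct`` / ``other_max_indoor_pct`` — extremes of the
      combined non-own-property share at indoor OPs;
    * ``outdoor_excess_max_pct`` — max over properties and flavours of
      100*(f_out - f_in_avg)/f_in_avg for the own-garden fraction.
    """
    out: dict = {
        "own_indoor_avg_pct": {},
        "own_indoor_by_property": {},
        "own_outdoor_by_property": {},
    }
    street, other = [], []
    excess = []
    for flavour, matrix in matrices.items():
        frac = fraction_table(matrix)
        own_in, own_out = {}, {}
        for prop in properties:
            rows = [frac.loc[f"{prop}:{op}"] for op in INDOOR_OPS]
            own_in[prop] = float(np.mean([r[prop] for r in rows]))
            own_out[prop] = float(frac.loc[f"{prop}:{OUTDOOR_OP}"][prop])
            street.extend(float(r["STREET"]) for r in rows)
            other.extend(1.0 - float(r[prop]) for r in rows)
            excess.append(100.0 * (own_out[prop] - own_in[prop])
                          / own_in[prop])
        out["own_indoor_by_property"][flavour] = {
            k: 100.0 * v for k, v in own_in.items()
        }
        out["own_outdoor_by_property"][flavour] = {
            k: 100.0 * v for k, v in own_out.items()
        }
        out["own_indoor_avg_pct"][flavour] = 100.0 * float(
            np.mean([own_in[p] for p in averaged_properties])
        )
    out["street_max_indoor_pct"] = 100.0 * max(street)
    out["other_min_indoor_pct"] = 100.0 * min(other)
    out["other_max_indoor_pct"] = 100.0 * max(other)
    out["outdoor_excess_max_pct"] = max(excess)
    return out


def top_cross_property(
    matrix_brick: pd.DataFrame, matrix_wood: pd.DataFrame, n: int = 10
) -> pd.DataFrame:
    """Ten highest single-OP contributions from another property's garden,
    with the brick and wooden flavours side by side (percent, 2 decimals)."""
    out = {}
    for name, matrix in (("brick_pct", matrix_brick), ("wood_pct", matrix_wood)):
        frac = fraction_table(matrix)
        for op, row in frac.iterrows():
            prop, room = _split_op(op)
            if room not in INDOOR_OPS:
                continue
            for region, f in row.items():
                if region.startswith("P") and region != prop:
                    out.setdefault((region, prop, room), {})[name] = round(
                        100.0 * f, 2
                    )
    df = pd.DataFrame(
        [
            {"source_property": k[0], "property": k[1], "room": k[2], **v}
            for k, v in out.items()
        ]
    )
    df["rank_key"] = df[["brick_pct", "wood_pct"]].max(axis=1)
    return (
        df.sort_values("rank_key", ascending=False)
        .drop(columns="rank_key")
        .head(n)
        .reset_index(drop=True)
    )
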