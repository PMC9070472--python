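"""Nearest-facility assignment, hub lines, bypass classification and
distance summaries.

Bypassing: an enrollee bypasses when the facility they actually use is not
among the facilities nearest to their recorded residence (Euclidean
straight-line distance; co-nearest facilities within a 1e-6 m tie
tolerance all count as "nearest").  Straight-line distance is the standard
proxy for travel cost where network and travel-time data are unavailable.

Report tables group by the facility USED — the patron population of each
facility — and print percentages at 1 dp and distances in km at 3 dp,
half-up, recomputed from counts rather than summed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ValidationError, round_half_up

__all__ = [
    "assign_nearest",
    "hub_lines",
    "bypass_table",
    "summarise_bypass_counts",
    "distance_summary",
    "summarise_distance_rows",
]

TIE_TOL_M = 1e-6


def assign_nearest(
    enrollees: pd.DataFrame,
    facilities: pd.DataFrame,
    accredited_only: bool = True,
) -> pd.DataFrame:
    """Assign each enrollee to the Euclidean-nearest facility and flag bypassing.

    With ``accredited_only`` (the default) only NHIS-accredited facilities
    are candidates — the set an insured person can actually use.  Ties
    within 1e-6 m resolve to the lexicographically smallest facility id for
    the ``nearest_facility_id`` column, while the full co-nearest set feeds
    the bypass flag, so an enrollee using ANY co-nearest facility is not a
    bypasser.

    Returns one row per enrollee: enrollee_id, nearest_facility_id,
    nearest_distance, used_facility_id, used_distance, bypassed.
    """
    fac = facilities
    if accredited_only:
        fac = facilities[facilities["nhis_accredited"].astype(bool)]
    if len(fac) == 0:
        raise ValidationError("no candidate facilities after accreditation filtering")
    fac_ids = fac["id"].astype(str).to_numpy()
    order = np.argsort(fac_ids)  # lexicographic tie-break comes free
    fac_ids = fac_ids[order]
    fxy = fac[["x", "y"]].to_numpy(dtype=float)[order]
    id_to_col = {fid: j for j, fid in enumerate(fac_ids)}

    exy = enrollees[["x", "y"]].to_numpy(dtype=float)
    used = enrollees["used_facility_id"].astype(str).to_numpy()
    unresolved = [
        (enrollees["id"].iloc[i], u) for i, u in enumerate(used) if u not in id_to_col
    ]
    if unresolved:
        eid, fid = unresolved[0]
        raise ValidationError(
            f"enrollee {eid}: used_facility_id {fid!r} does not resolve against the "
            "candidate facility table"
        )
    used_col = np.array([id_to_col[u] for u in used])

    n = len(exy)
    nearest_idx = np.empty(n, dtype=int)
    nearest_d = np.empty(n)
    used_d = np.empty(n)
    bypassed = np.empty(n, dtype=bool)
    chunk = max(1, 4_000_000 // max(len(fac_ids), 1))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = np.sqrt(((exy[start:stop, None, :] - fxy[None, :, :]) ** 2).sum(axis=2))
        dmin = d.min(axis=1)
        # first index at the minimum = smallest id thanks to the sort above
        nearest_idx[start:stop] = np.argmax(d <= dmin[:, None] + TIE_TOL_M, axis=1)
        nearest_d[start:stop] = dmin
        ud = d[np.arange(stop - start), used_col[start:stop]]
        used_d[start:stop] = ud
        bypassed[start:stop] = ud > dmin + TIE_TOL_M
    return pd.DataFrame(
        {
            "enrollee_id": enrollees["id"].astype(str).to_numpy(),
            "nearest_facility_id": fac_ids[nearest_idx],
            "nearest_distance": nearest_d,
            "used_facility_id": used,
            "used_distance": used_d,
            "bypassed": bypassed,
        }
    )


def hub_lines(
    assignments: pd.DataFrame,
    enrollees: pd.DataFrame,
    facilities: pd.DataFrame,
    which: str = "used",
) -> list[dict]:
    """Straight LineString features from each residence to a facility.

    ``which`` selects the endpoint: the nearest facility or the one
    actually used.  Each feature carries {enrollee_id, facility_id,
    distance_m, bypassed} — the spider-web diagram of patient flows, ready
    for :func:`geoaccess.io.write_geojson`.
    """
    if which not in ("nearest", "used"):
        raise ValidationError(f"which must be 'nearest' or 'used', got {which!r}")
    fid_col = "nearest_facility_id" if which == "nearest" else "used_facility_id"
    dist_col = "nearest_distance" if which == "nearest" else "used_distance"
    epos = {
        str(r["id"]): (float(r["x"]), float(r["y"])) for _, r in enrollees.iterrows()
    }
    fpos = {
        str(r["id"]): (float(r["x"]), float(r["y"])) for _, r in facilities.iterrows()
    }
    features = []
    for _, row in assignments.iterrows():
        eid = str(row["enrollee_id"])
        fid = str(row[fid_col])
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [list(epos[eid]), list(fpos[fid])],
                },
                "properties": {
                    "enrollee_id": eid,
                    "facility_id": fid,
                    "distance_m": float(row[dist_col]),
                    "bypassed": bool(row["bypassed"]),
                },
            }
        )
    return features


def summarise_bypass_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Bypass rate table from per-facility (n_bypassed, n_non_bypassed) counts.

    Adds n_patrons and 1-dp percentages per facility plus a Total row whose
    percentages are recomputed from the summed counts (never averaged).
    """
    req = {"facility_id", "n_bypassed", "n_non_bypassed"}
    missing = req - set(counts.columns)
    if missing:
        raise ValidationError(f"bypass counts table is missing column(s): {sorted(missing)}")
    rows = []
    for _, r in counts.iterrows():
        nb, nn = int(r["n_bypassed"]), int(r["n_non_bypassed"])
        total = nb + nn
        rows.append(
            {
                "facility_id": str(r["facility_id"]),
                "n_patrons": total,
                "n_bypassed": nb,
                "pct_bypassed": round_half_up(100.0 * nb / total, 1) if total else 0.0,
                "n_non_bypassed": nn,
                "pct_non_bypassed": round_half_up(100.0 * nn / total, 1) if total else 0.0,
            }
        )
    tb = sum(r["n_bypassed"] for r in rows)
    tn = sum(r["n_non_bypassed"] for r in rows)
    tt = tb + tn
    rows.append(
        {
            "facility_id": "Total",
            "n_patrons": tt,
            "n_bypassed": tb,
            "pct_bypassed": round_half_up(100.0 * tb / tt, 1) if tt else 0.0,
            "n_non_bypassed": tn,
            "pct_non_bypassed": round_half_up(100.0 * tn / tt, 1) if tt else 0.0,
        }
    )
    return pd.DataFrame(rows)


def bypass_table(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-facility bypassing status of the patrons of each USED facility."""
    if len(assignments) == 0:
        raise ValidationError("bypass_table needs a non-empty assignment table")
    grouped = (
        assignments.assign(bypassed=assignments["bypassed"].astype(bool))
        .groupby("used_facility_id", sort=True)["bypassed"]
        .agg(n_bypassed="sum", n_patrons="count")
        .reset_index()
        .rename(columns={"used_facility_id": "facility_id"})
    )
    grouped["n_bypassed"] = grouped["n_bypassed"].astype(int)
    grouped["n_non_bypassed"] = grouped["n_patrons"] - grouped["n_bypassed"]
    return summarise_bypass_counts(grouped[["facility_id", "n_bypassed", "n_non_bypassed"]])


def summarise_distance_rows(rows: pd.DataFrame) -> pd.DataFrame:
    """Append the unweighted column-mean row to per-facility km distances.

    ``rows`` has columns facility_id, shortest_km, longest_km (3 dp).  The
    final row averages each column across facilities and is itself printed
    at 3 dp.
    """
    req = {"facility_id", "shortest_km", "longest_km"}
    missing = req - set(rows.columns)
    if missing:
        raise ValidationError(f"distance table is missing column(s): {sorted(missing)}")
    out = rows[["facility_id", "shortest_km", "longest_km"]].copy()
    mean_row = {
        "facility_id": "Average",
        "shortest_km": round_half_up(float(out["shortest_km"].mean()), 3),
        "longest_km": round_half_up(float(out["longest_km"].mean()), 3),
    }
    return pd.concat([out, pd.DataFrame([mean_row])], ignore_index=True)


def distance_summary(assignments: pd.DataFrame) -> pd.DataFrame:
    """Shortest/longest distance travelled to each used facility, in km (3 dp).

    Groups by the facility used; per facility the row is the min and max of
    the distances its patrons travelled; facilities without patrons do not
    appear.  The final row is the unweighted mean of each column over
    facilities.
    """
    if len(assignments) == 0:
        raise ValidationError("distance_summary needs a non-empty assignment table")
    g = assignments.groupby("used_facility_id", sort=True)["used_distance"]
    rows = pd.DataFrame(
        {
            "facility_id": list(g.groups.keys()),
            "shortest_km": [round_half_up(v / 1000.0, 3) for v in g.min()],
            "longest_km": [round_half_up(v / 1000.0, 3) for v in g.max()],
        }
    )
    return summarise_distance_rows(rows)
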