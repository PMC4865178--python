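"""Domain types and dataset I/O for repeated Prisoner's Dilemma experiments.

The central containers are :class:`GameStructure` (the institutional design of
one experiment: payoff indices, continuation probability, noise, framing
flags), :class:`ActionRecord` (one player's one decision at one period of one
paired interaction), and :class:`Dataset` (a structure table plus a decision
table, mirroring the hierarchy *game structure -> interaction -> period ->
simultaneous actions*).

Decision data are stored as a pandas DataFrame with one row per
(structure, interaction, player, period).  Lagged action columns (``my_prev``,
``other_prev``) are always derived from the action stream at load time, never
read from input files, so there is a single source of truth for history.
Actions are coded Cooperate = 1, Defect = 0 throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GameStructure",
    "ActionRecord",
    "Dataset",
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "table2_fixtures",
    "RECORD_COLUMNS",
]

#: canonical decision-table columns (lag columns are derived, see Dataset.from_actions)
RECORD_COLUMNS = ("structure_id", "interaction_id", "player_id", "period", "action")

_PD_TOL = 1e-9


class DatasetError(ValueError):
    """Raised when an input file or constructed dataset violates an invariant."""


@dataclass(frozen=True)
class GameStructure:
    """Institutional specification of one repeated Prisoner's Dilemma design.

    Parameters
    ----------
    id : str
        Structure label, unique within a dataset.
    r1 : float
        Normalized payoff index (R-P)/(T-S): gain of mutual cooperation over
        mutual defection.  Classic index of the "cooperativeness" of the game.
    r2 : float
        Normalized payoff index (R-S)/(T-S): gain from the opponent
        cooperating rather than defecting while oneself cooperates.
    delta : float
        Continuation probability.  For indefinitely repeated games, the
        per-period probability the interaction continues; for fixed-length
        games, the value implied by the expected-length convention
        E[len] = 1/(1-delta).
    error : float
        Probability in [0, 0.5] that a chosen action is exogenously flipped
        before implementation.
    infinite, continuous, risk : int
        0/1 indicators: stochastic termination, continuous-time play
        (discretized to subperiods), and stochastic payoffs.
    payoffs : tuple, optional
        Raw (R, S, T, P) in experiment currency units.  When present they
        must satisfy the Prisoner's Dilemma ordering T > R > P > S and
        R > (S+T)/2, and must reproduce (r1, r2) to 1e-9.
    cooperation : float, optional
        Observed mean cooperation in the source experiment (metadata).
    source : str, optional
        Source-experiment label (metadata).
    """

    id: str
    r1: float
    r2: float
    delta: float
    error: float
    infinite: int
    continuous: int
    risk: int
    payoffs: tuple[float, float, float, float] | None = None
    cooperation: float | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.r1 <= 1.0 or not 0.0 <= self.r2 <= 1.0:
            raise DatasetError(f"structure {self.id}: r1/r2 must lie in [0,1]")
        if not 0.0 < self.delta < 1.0:
            raise DatasetError(f"structure {self.id}: delta must lie in (0,1)")
        if not 0.0 <= self.error <= 0.5:
            raise DatasetError(f"structure {self.id}: error must lie in [0,0.5]")
        for name in ("infinite", "continuous", "risk"):
            if getattr(self, name) not in (0, 1):
                raise DatasetError(f"structure {self.id}: {name} must be 0 or 1")
        if self.payoffs is not None:
            R, S, T, P = self.payoffs
            if not (T > R > P > S):
                raise DatasetError(
                    f"structure {self.id}: payoffs must satisfy T > R > P > S"
                )
            if not R > (S + T) / 2:
                raise DatasetError(
                    f"structure {self.id}: payoffs must satisfy R > (S+T)/2"
                )
            r1 = (R - P) / (T - S)
            r2 = (R - S) / (T - S)
            if abs(r1 - self.r1) > _PD_TOL or abs(r2 - self.r2) > _PD_TOL:
                raise DatasetError(
                    f"structure {self.id}: payoffs imply (r1, r2)=({r1:.6g}, {r2:.6g}), "
                    f"inconsistent with declared ({self.r1}, {self.r2})"
                )


class ActionRecord(NamedTuple):
    """One player's decision at one period of one paired interaction."""

    structure_id: str
    interaction_id: str
    player_id: str
    period: int
    action: int
    my_prev: int | None
    other_prev: int | None


@dataclass
class Dataset:
    """A structure table plus a decision table with derived lag columns."""

    structures: dict[str, GameStructure]
    records: pd.DataFrame

    # ------------------------------------------------------------------ build
    @classmethod
    def from_actions(
        cls,
        structures: Iterable[GameStructure],
        actions: pd.DataFrame,
        validate: bool = True,
    ) -> "Dataset":
        """Build a dataset from raw (structure, interaction, player, period,
        action) rows, deriving ``my_prev`` and ``other_prev``.

        Lag derivation: within each interaction, ``my_prev`` at period t is the
        same player's action at t-1, and ``other_prev`` is the *other*
        player's action at t-1.  Both are missing exactly at period 1.
        """
        struct_map = {g.id: g for g in structures}
        df = actions.loc[:, list(RECORD_COLUMNS)].copy()
        df["period"] = df["period"].astype(int)
        df["action"] = df["action"].astype(int)
        if not df["action"].isin((0, 1)).all():
            bad = df.loc[~df["action"].isin((0, 1))].index[0]
            raise DatasetError(f"row {bad}: action must be 0 or 1")
        df = df.sort_values(
            ["structure_id", "interaction_id", "player_id", "period"], kind="stable"
        ).reset_index(drop=True)

        prev = df[["interaction_id", "player_id", "period", "action"]].copy()
        prev["period"] = prev["period"] + 1
        # own lag
        df = df.merge(
            prev.rename(columns={"action": "my_prev"}),
            on=["interaction_id", "player_id", "period"],
            how="left",
        )
        # opponent lag: join on interaction/period, keep the other player's row
        other = prev.rename(
            columns={"player_id": "_opp", "action": "other_prev"}
        )
        df = df.merge(other, on=["interaction_id", "period"], how="left")
        df = df[(df["_opp"].isna()) | (df["_opp"] != df["player_id"])]
        df = df.drop(columns=["_opp"]).reset_index(drop=True)

        ds = cls(structures=struct_map, records=df)
        if validate:
            ds.validate()
        return ds

    # --------------------------------------------------------------- validate
    def validate(self) -> None:
        df = self.records
        unknown = set(df["structure_id"]) - set(self.structures)
        if unknown:
            raise DatasetError(f"records reference unknown structures: {sorted(unknown)}")

        grp = df.groupby("interaction_id", sort=False)
        nplayers = grp["player_id"].nunique()
        bad = nplayers[nplayers != 2]
        if len(bad):
            raise DatasetError(
                f"interaction {bad.index[0]!r} has {int(bad.iloc[0])} players; "
                "exactly 2 required"
            )
        # simultaneous play: every (interaction, period) has both players
        per_period = df.groupby(["interaction_id", "period"], sort=False)[
            "player_id"
        ].nunique()
        bad = per_period[per_period != 2]
        if len(bad):
            inter, period = bad.index[0]
            raise DatasetError(
                f"interaction {inter!r} period {period} is missing one player's action"
            )
        # consecutive 1-based periods per (interaction, player)
        for (inter, _player), sub in df.groupby(
            ["interaction_id", "player_id"], sort=False
        ):
            p = np.sort(sub["period"].to_numpy())
            if p[0] != 1 or not np.array_equal(p, np.arange(1, len(p) + 1)):
                raise DatasetError(
                    f"interaction {inter!r}: periods must be consecutive from 1"
                )
        # lag missingness pattern
        first = df["period"] == 1
        if df.loc[first, ["my_prev", "other_prev"]].notna().any().any():
            raise DatasetError("period-1 records must not carry lagged actions")
        if df.loc[~first, ["my_prev", "other_prev"]].isna().any().any():
            raise DatasetError("records beyond period 1 must carry lagged actions")

    # ------------------------------------------------------------------ views
    def to_records(self) -> list[ActionRecord]:
        out = []
        for row in self.records.itertuples(index=False):
            out.append(
                ActionRecord(
                    row.structure_id,
                    row.interaction_id,
                    row.player_id,
                    int(row.period),
                    int(row.action),
                    None if pd.isna(row.my_prev) else int(row.my_prev),
                    None if pd.isna(row.other_prev) else int(row.other_prev),
                )
            )
        return out

    def subset(self, structure_ids: Iterable[str]) -> "Dataset":
        """Restrict to the given structures (used by cross-validation folds)."""
        keep = set(structure_ids)
        return Dataset(
            structures={k: v for k, v in self.structures.items() if k in keep},
            records=self.records[self.records["structure_id"].isin(keep)].reset_index(
                drop=True
            ),
        )

    @property
    def n_decisions(self) -> int:
        return len(self.records)


def pivot_interactions(records: pd.DataFrame):
    """Pivot one structure's decision rows into dense period-major arrays.

    Returns ``(interaction_ids, players, actions)`` where ``actions`` has
    shape (2, n_interactions, T_max) with NaN padding beyond each
    interaction's length, slot 0 holding the lexicographically smaller
    player id of each interaction.  Used by learning-rule replay and by
    period-by-period prediction walkers.
    """
    sub = records.sort_values(
        ["interaction_id", "player_id", "period"], kind="stable"
    )
    inter_codes, inter_ids = pd.factorize(sub["interaction_id"], sort=True)
    first = sub.groupby("interaction_id")["player_id"].transform("min")
    slot = (sub["player_id"] != first).to_numpy().astype(int)
    t_max = int(sub["period"].max())
    n_inter = len(inter_ids)
    actions = np.full((2, n_inter, t_max), np.nan)
    actions[slot, inter_codes, sub["period"].to_numpy() - 1] = sub[
        "action"
    ].to_numpy(dtype=float)
    players = np.empty((2, n_inter), dtype=object)
    players[slot, inter_codes] = sub["player_id"].to_numpy()
    return list(inter_ids), players, actions


# --------------------------------------------------------------------- dialect

_DEFAULT_DIALECT: dict[str, str] = {c: c for c in RECORD_COLUMNS}

_STRUCT_COLUMNS = {
    "id": "id",
    "r1": "r1",
    "r2": "r2",
    "delta": "delta",
    "error": "error",
    "infinite": "infinite",
    "continuous": "continuous",
    "risk": "risk",
}


def _load_dialect(dialect) -> tuple[dict[str, str], dict[str, str]]:
    """A dialect maps canonical column names to the file's column names.

    Accepts None, a mapping with optional ``decisions``/``structures``
    sub-mappings, or a path to a YAML/JSON file holding such a mapping.
    """
    if dialect is None:
        return dict(_DEFAULT_DIALECT), dict(_STRUCT_COLUMNS)
    if isinstance(dialect, (str, Path)):
        import yaml

        with open(dialect) as fh:
            dialect = yaml.safe_load(fh)
    dec = dict(_DEFAULT_DIALECT)
    struct = dict(_STRUCT_COLUMNS)
    dec.update(dialect.get("decisions", {}))
    struct.update(dialect.get("structures", {}))
    return dec, struct


def _read_structures(path, colmap: Mapping[str, str]) -> list[GameStructure]:
    df = pd.read_csv(path)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise DatasetError(f"{path}: structure table missing columns {missing}")
    has_payoffs = all(c in df.columns for c in ("R", "S", "T", "P"))
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = df.iloc[i - 2]
        try:
            payoffs = None
            if has_payoffs and not d[["R", "S", "T", "P"]].isna().any():
                payoffs = tuple(float(d[c]) for c in ("R", "S", "T", "P"))
            out.append(
                GameStructure(
                    id=str(d[colmap["id"]]),
                    r1=float(d[colmap["r1"]]),
                    r2=float(d[colmap["r2"]]),
                    delta=float(d[colmap["delta"]]),
                    error=float(d[colmap["error"]]),
                    infinite=int(d[colmap["infinite"]]),
                    continuous=int(d[colmap["continuous"]]),
                    risk=int(d[colmap["risk"]]),
                    payoffs=payoffs,
                    cooperation=(
                        float(d["cooperation"])
                        if "cooperation" in df.columns and not pd.isna(d["cooperation"])
                        else None
                    ),
                    source=(
                        str(d["source"])
                        if "source" in df.columns and not pd.isna(d["source"])
                        else None
                    ),
                )
            )
        except (ValueError, TypeError) as exc:
            raise DatasetError(f"{path} line {i}: {exc}") from exc
    return out


def read_dataset(decisions_path, structures_path, dialect=None) -> Dataset:
    """Read a decision table and a structure table and join them.

    The decision file needs the columns ``structure_id, interaction_id,
    player_id, period, action`` (renameable via *dialect*); lag columns in the
    file, if any, are ignored and re-derived from the action stream.
    """
    dec_map, struct_map = _load_dialect(dialect)
    structures = _read_structures(structures_path, struct_map)
    raw = pd.read_csv(decisions_path)
    missing = [v for v in dec_map.values() if v not in raw.columns]
    if missing:
        raise DatasetError(f"{decisions_path}: decision table missing columns {missing}")
    df = raw.rename(columns={v: k for k, v in dec_map.items()})
    for col in ("period", "action"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header + 1-based
            raise DatasetError(f"{decisions_path} line {line}: non-numeric {col!r}")
    df["structure_id"] = df["structure_id"].astype(str)
    df["interaction_id"] = df["interaction_id"].astype(str)
    df["player_id"] = df["player_id"].astype(str)
    return Dataset.from_actions(structures, df)


def write_dataset(ds: Dataset, decisions_path, structures_path) -> None:
    """Write the dataset back to the standard two-file CSV layout."""
    ds.records.loc[:, list(RECORD_COLUMNS)].to_csv(decisions_path, index=False)
    rows = []
    for g in ds.structures.values():
        row = {
            "id": g.id,
            "r1": g.r1,
            "r2": g.r2,
            "delta": g.delta,
            "error": g.error,
            "infinite": g.infinite,
            "continuous": g.continuous,
            "risk": g.risk,
            "cooperation": g.cooperation,
            "source": g.source,
        }
        if g.payoffs is not None:
            row.update(zip("RSTP", g.payoffs))
        rows.append(row)
    pd.DataFrame(rows).to_csv(structures_path, index=False)


# --------------------------------------------------------------- fixtures

# The thirty published game structures of the combined dataset:
# (error, delta, infinite, continuous, risk, r1, r2, observed cooperation, source).
_TABLE2 = (
    (0.0000, 0.900, 0, 0, 0, 0.18, 0.590, 0.60, "BR"),
    (0.0000, 0.900, 0, 0, 1, 0.18, 0.590, 0.35, "BR"),
    (0.0000, 0.900, 1, 0, 0, 0.33, 0.670, 0.56, "DO"),
    (0.0000, 0.900, 0, 0, 1, 0.33, 0.830, 0.31, "KS"),
    (0.0000, 0.900, 0, 0, 0, 0.33, 0.830, 0.57, "KS"),
    (0.0000, 0.500, 1, 0, 0, 0.18, 0.530, 0.10, "DF"),
    (0.0000, 0.750, 1, 0, 0, 0.18, 0.530, 0.20, "DF"),
    (0.0000, 0.500, 1, 0, 0, 0.39, 0.740, 0.18, "DF"),
    (0.0000, 0.750, 1, 0, 0, 0.39, 0.740, 0.59, "DF"),
    (0.0000, 0.750, 1, 0, 0, 0.61, 0.950, 0.76, "DF"),
    (0.0000, 0.500, 1, 0, 0, 0.61, 0.950, 0.35, "DF"),
    (0.1250, 0.875, 1, 0, 0, 0.20, 0.600, 0.34, "FR"),
    (0.1250, 0.875, 1, 0, 0, 0.33, 0.660, 0.49, "FR"),
    (0.1250, 0.875, 1, 0, 0, 0.43, 0.710, 0.59, "FR"),
    (0.0000, 0.875, 1, 0, 0, 0.60, 0.800, 0.74, "FR"),
    (0.0625, 0.875, 1, 0, 0, 0.60, 0.800, 0.78, "FR"),
    (0.1250, 0.875, 1, 0, 0, 0.60, 0.800, 0.57, "FR"),
    (0.0000, 0.900, 0, 0, 0, 0.25, 0.583, 0.43, "AM"),
    (0.0000, 0.875, 0, 1, 0, 0.11, 0.560, 0.27, "FO"),
    (0.0000, 0.875, 0, 1, 0, 0.14, 0.710, 0.33, "FO"),
    (0.0000, 0.875, 0, 1, 0, 0.33, 0.560, 0.54, "FO"),
    (0.0000, 0.875, 0, 1, 0, 0.43, 0.710, 0.62, "FO"),
    (0.0000, 0.500, 0, 0, 0, 0.33, 0.610, 0.12, "DB"),
    (0.0000, 0.750, 0, 0, 0, 0.33, 0.610, 0.24, "DB"),
    (0.0000, 0.750, 0, 0, 0, 0.33, 0.720, 0.25, "DB"),
    (0.0000, 0.500, 0, 0, 0, 0.33, 0.720, 0.13, "DB"),
    (0.0000, 0.500, 1, 0, 0, 0.33, 0.610, 0.23, "DB"),
    (0.0000, 0.750, 1, 0, 0, 0.33, 0.610, 0.35, "DB"),
    (0.0000, 0.750, 1, 0, 0, 0.33, 0.720, 0.36, "DB"),
    (0.0000, 0.500, 1, 0, 0, 0.33, 0.720, 0.31, "DB"),
)


def table2_fixtures() -> list[GameStructure]:
    """The 30 published game structures of the combined dataset.

    Ids are "01".."30" in publication order; observed cooperation and the
    source-experiment label are attached as metadata.  Raw payoffs are not
    published at the structure level, so ``payoffs`` is None throughout.
    """
    out = []
    for i, (error, delta, inf, cont, risk, r1, r2, coop, src) in enumerate(
        _TABLE2, start=1
    ):
        out.append(
            GameStructure(
                id=f"{i:02d}",
                r1=r1,
                r2=r2,
                delta=delta,
                error=error,
                infinite=inf,
                continuous=cont,
                risk=risk,
                cooperation=coop,
                source=src,
            )
        )
    return out
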