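"""Longitudinal dendritic-spine turnover and persistence statistics.

The input is a long-format presence table: one row per (dendrite, spine,
session) with a binary ``present`` flag and an optional morphology label.
Between consecutive sessions a spine present at both is *stable*, a spine
present only at the earlier one is *eliminated*, and a spine present only at
the later one is *formed* (a reappearing spine id counts as a new formation
event). Elimination and formation rates are percentages of the previous
session's total; spine density is spines per µm of dendrite.

The persistence index of a spine is the fraction of subsequent imaging
sessions at which it remains present: for pre-existing spines (present at
every baseline session) the post-baseline sessions are scored, for newly
formed spines the sessions strictly after the birth session. A second
convention scoring all sessions from the first baseline (pre-existing) or
from birth (newly formed) is available via ``denominator="all_sessions"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import UNDEFINED

__all__ = [
    "TransitionCounts",
    "PersistenceRecord",
    "validate_table",
    "classify_transitions",
    "spine_density",
    "turnover_rates",
    "persistence_index",
    "persistence_table",
    "morphology_fractions",
    "aggregate",
]

REQUIRED_COLUMNS = (
    "animal_id",
    "dendrite_id",
    "dendrite_length_um",
    "spine_id",
    "session",
    "present",
)


@dataclass(frozen=True)
class TransitionCounts:
    """Spine transition counts for one dendrite and session pair."""

    dendrite_id: str
    session_prev: str
    session_curr: str
    n_prev: int
    n_stable: int
    n_eliminated: int
    n_formed: int
    n_curr: int

    def __post_init__(self) -> None:
        assert self.n_stable + self.n_eliminated == self.n_prev
        assert self.n_stable + self.n_formed == self.n_curr


@dataclass(frozen=True)
class PersistenceRecord:
    spine_id: str
    spine_class: str  # pre_existing | newly_formed
    birth_session: str
    persistence_index: float  # nan when the denominator is empty


def validate_table(table: pd.DataFrame, session_order: list[str]) -> None:
    """Check schema, session labels and key uniqueness; raise on violation."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"spine table missing required columns: {missing}")
    unknown = set(table["session"]) - set(session_order)
    if unknown:
        raise ValueError(f"unknown session labels not in session order: {sorted(unknown)}")
    if (table["dendrite_length_um"] <= 0).any():
        raise ValueError("dendrite_length_um must be > 0 for every row")
    dup = table.duplicated(subset=["dendrite_id", "spine_id", "session"])
    if dup.any():
        rows = table.index[dup].tolist()[:5]
        raise ValueError(f"duplicate (dendrite, spine, session) keys at rows {rows}")


def _presence_sets(table: pd.DataFrame, session: str) -> pd.Series:
    sub = table[(table["session"] == session) & (table["present"] == 1)]
    return sub.groupby("dendrite_id")["spine_id"].agg(set)


def classify_transitions(
    table: pd.DataFrame, session_order: list[str]
) -> list[TransitionCounts]:
    """Stable / eliminated / formed counts for every consecutive session pair.

    A spine absent at the earlier session (or never yet seen) and present at
    the later one counts as formed; rows before a spine's birth are simply
    missing from the table.
    """
    if len(session_order) < 2:
        raise ValueError("transition classification requires at least two sessions")
    validate_table(table, session_order)
    dendrites = sorted(table["dendrite_id"].unique())
    present = {s: _presence_sets(table, s) for s in session_order}
    out: list[TransitionCounts] = []
    for prev, curr in zip(session_order[:-1], session_order[1:]):
        for d in dendrites:
            p: set = present[prev].get(d, set())
            c: set = present[curr].get(d, set())
            out.append(
                TransitionCounts(
                    dendrite_id=d,
                    session_prev=prev,
                    session_curr=curr,
                    n_prev=len(p),
                    n_stable=len(p & c),
                    n_eliminated=len(p - c),
                    n_formed=len(c - p),
                    n_curr=len(c),
                )
            )
    return out


def spine_density(table: pd.DataFrame, session: str) -> pd.DataFrame:
    """Spines per µm of dendrite at one session, per dendrite."""
    if (table["dendrite_length_um"] <= 0).any():
        raise ValueError("dendrite_length_um must be > 0")
    lengths = table.groupby("dendrite_id")["dendrite_length_um"].first()
    counts = (
        table[(table["session"] == session) & (table["present"] == 1)]
        .groupby("dendrite_id")["spine_id"]
        .nunique()
        .reindex(lengths.index, fill_value=0)
    )
    return pd.DataFrame(
        {
            "dendrite_id": lengths.index,
            "session": session,
            "n_spines": counts.values,
            "density_per_um": counts.values / lengths.values,
        }
    ).reset_index(drop=True)


def turnover_rates(counts: list[TransitionCounts]) -> pd.DataFrame:
    """Percent eliminated / formed / stable relative to the previous total.

    Session pairs with no spines at the previous session get NaN markers and
    are excluded from any later aggregation rather than raising.
    """
    rows = []
    for c in counts:
        if c.n_prev > 0:
            elim = 100.0 * c.n_eliminated / c.n_prev
            form = 100.0 * c.n_formed / c.n_prev
            stable = 100.0 * c.n_stable / c.n_prev
        else:
            elim = form = stable = UNDEFINED
        rows.append(
            {
                "dendrite_id": c.dendrite_id,
                "session_prev": c.session_prev,
                "session_curr": c.session_curr,
                "n_prev": c.n_prev,
                "elimination_rate_pct": elim,
                "formation_rate_pct": form,
                "stable_fraction_pct": stable,
            }
        )
    return pd.DataFrame(rows)


def _spine_code(
    table: pd.DataFrame, dendrite_id: str, spine_id: str, session_order: list[str]
) -> np.ndarray:
    """Presence vector over the full session order (absent rows are 0)."""
    sub = table[(table["dendrite_id"] == dendrite_id) & (table["spine_id"] == spine_id)]
    if sub.empty:
        raise ValueError(f"spine {spine_id!r} not found on dendrite {dendrite_id!r}")
    code = np.zeros(len(session_order), dtype=int)
    idx = {s: i for i, s in enumerate(session_order)}
    for _, row in sub.iterrows():
        code[idx[row["session"]]] = int(row["present"])
    return code


def persistence_from_code(
    code: np.ndarray,
    baseline_idx: list[int],
    denominator: str = "post_baseline",
) -> tuple[str, int, float]:
    """Persistence index of one binary presence code.

    Returns (class, birth index, index value). Pre-existing spines are
    present at every baseline session and are scored over post-baseline
    sessions; newly formed spines over sessions strictly after birth. The
    ``all_sessions`` convention instead divides the presence sum over all
    scored-and-defining sessions (from the first baseline, or from birth) by
    their count. A newly formed spine born at the final session has an empty
    post-birth window and gets a NaN index under ``post_baseline``.
    """
    code = np.asarray(code, dtype=int)
    if denominator not in ("post_baseline", "all_sessions"):
        raise ValueError(f"unknown denominator convention {denominator!r}")
    if not baseline_idx:
        raise ValueError("at least one baseline session is required")
    last_baseline = max(baseline_idx)
    pre_existing = all(code[i] == 1 for i in baseline_idx)
    if pre_existing:
        birth = int(np.flatnonzero(code == 1)[0])
        if denominator == "post_baseline":
            window = code[last_baseline + 1 :]
        else:
            window = code[min(baseline_idx) :]
        idx_val = float(window.mean()) if window.size else UNDEFINED
        return "pre_existing", birth, idx_val
    born = np.flatnonzero(code == 1)
    if born.size == 0:
        raise ValueError("spine never present in the table")
    birth = int(born[0])
    if denominator == "post_baseline":
        window = code[birth + 1 :]
    else:
        window = code[birth:]
    idx_val = float(window.mean()) if window.size else UNDEFINED
    return "newly_formed", birth, idx_val


def persistence_index(
    table: pd.DataFrame,
    dendrite_id: str,
    spine_id: str,
    session_order: list[str],
    baseline_sessions: list[str],
    denominator: str = "post_baseline",
) -> PersistenceRecord:
    """Persistence record for a single spine (see module docstring)."""
    bad = [s for s in baseline_sessions if s not in session_order]
    if bad:
        raise ValueError(f"baseline sessions not in session order: {bad}")
    code = _spine_code(table, dendrite_id, spine_id, session_order)
    baseline_idx = [session_order.index(s) for s in baseline_sessions]
    cls, birth, val = persistence_from_code(code, baseline_idx, denominator)
    return PersistenceRecord(
        spine_id=spine_id,
        spine_class=cls,
        birth_session=session_order[birth],
        persistence_index=val,
    )


def persistence_table(
    table: pd.DataFrame,
    session_order: list[str],
    baseline_sessions: list[str],
    denominator: str = "post_baseline",
) -> pd.DataFrame:
    """Persistence indices for every spine in the table (vectorized)."""
    validate_table(table, session_order)
    bad = [s for s in baseline_sessions if s not in session_order]
    if bad:
        raise ValueError(f"baseline sessions not in session order: {bad}")
    idx = {s: i for i, s in enumerate(session_order)}
    baseline_idx = [idx[s] for s in baseline_sessions]
    wide = (
        table.assign(si=table["session"].map(idx))
        .pivot_table(
            index=["dendrite_id", "spine_id"],
            columns="si",
            values="present",
            aggfunc="first",
            fill_value=0,
        )
        .reindex(columns=range(len(session_order)), fill_value=0)
    )
    rows = []
    for (d, sp), code in zip(wide.index, wide.to_numpy(dtype=int)):
        cls, birth, val = persistence_from_code(code, baseline_idx, denominator)
        rows.append(
            {
                "dendrite_id": d,
                "spine_id": sp,
                "spine_class": cls,
                "birth_session": session_order[birth],
                "persistence_index": val,
            }
        )
    return pd.DataFrame(rows)


def morphology_fractions(
    table: pd.DataFrame, session: str, dendrite_id: str
) -> dict[str, float]:
    """Fractions of mushroom/thin/stubby among spines present at a session."""
    sub = table[
        (table["session"] == session)
        & (table["dendrite_id"] == dendrite_id)
        & (table["present"] == 1)
    ]
    if sub.empty:
        return {t: UNDEFINED for t in ("mushroom", "thin", "stubby")}
    unlabeled = sub[sub["morph_type"].isna() | (sub["morph_type"] == "")]
    if len(unlabeled):
        raise ValueError(
            "missing morphology labels for spines: "
            f"{sorted(unlabeled['spine_id'].tolist())}"
        )
    counts = sub["morph_type"].value_counts()
    n = len(sub)
    return {t: float(counts.get(t, 0)) / n for t in ("mushroom", "thin", "stubby")}


def aggregate(
    series: pd.DataFrame,
    value_columns: list[str],
    by: str = "dendrite_id",
    group_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Mean ± SEM per group, NaN markers excluded and counted.

    ``by`` names the replication unit column; ``group_columns`` (e.g. the
    session pair) define the cells. SEM is sd/sqrt(n) with ddof=1 and is NaN
    for a single value.
    """
    group_columns = group_columns or []
    out_rows = []
    grouped = series.groupby(group_columns) if group_columns else [((), series)]
    for key, sub in grouped:
        if not isinstance(key, tuple):
            key = (key,)
        for col in value_columns:
            vals = sub.groupby(by)[col].mean()  # one value per unit
            defined = vals.dropna()
            n = len(defined)
            mean = float(defined.mean()) if n else UNDEFINED
            sem = float(defined.std(ddof=1) / np.sqrt(n)) if n > 1 else UNDEFINED
            out_rows.append(
                dict(
                    zip(group_columns, key),
                    statistic=col,
                    mean=mean,
                    sem=sem,
                    n=n,
                    n_excluded=int(len(vals) - n),
                )
            )
    return pd.DataFrame(out_rows)
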