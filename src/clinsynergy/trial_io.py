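"""Trial records, agent canonicalization, and tabular input/output.

The unit of data is one Phase II trial arm: the agents administered, the
number of responders ``n`` out of ``N`` treated patients, and the cancer
type. Agent names are canonicalized through an :class:`AgentRegistry`
(case-insensitive synonym lookup) so that trials testing the same
combination key together regardless of naming or agent order.

Trials are read from comma-separated text with a header row; the
``agents`` cell uses ``;`` between agent names so that the comma stays
reserved for the column delimiter. Radiation counts as an agent: the
catalogs this tool emulates treat chemoradiation arms as combinations.
"""

from __future__ import annotations

import json
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "TrialRecord",
    "Combination",
    "AgentRegistry",
    "TrialFormatError",
    "TrialValidationError",
    "read_trials",
    "write_trials",
    "write_catalog",
    "group_by_combination",
    "flag_monoclonal",
]

REQUIRED_COLUMNS = ("trial_id", "agents", "n_responders", "sample_size", "cancer_type")


class TrialFormatError(ValueError):
    """The input table does not have the expected layout."""


class TrialValidationError(ValueError):
    """A row or value violates a data-model invariant."""


def _canonical_key(name: str) -> str:
    return name.strip().lower()


@dataclass(frozen=True)
class Combination:
    """An order-insensitive set of agents identifying what a trial tested."""

    agents: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "agents", tuple(sorted(self.agents)))
        if len(self.agents) == 0:
            raise TrialValidationError("a combination needs at least one agent")
        if len(set(self.agents)) != len(self.agents):
            raise TrialValidationError(f"duplicate agent in combination {self.agents}")

    @property
    def size(self) -> int:
        return len(self.agents)

    def __str__(self) -> str:
        return " + ".join(self.agents)


@dataclass(frozen=True)
class TrialRecord:
    """One trial arm: agents, responders ``n`` out of sample size ``N``."""

    trial_id: str
    agents: tuple[str, ...]
    n_responders: int
    sample_size: int
    cancer_type: str = ""
    year: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "agents", tuple(self.agents))
        if len(self.agents) == 0:
            raise TrialValidationError(f"trial {self.trial_id!r}: no agents")
        if len({_canonical_key(a) for a in self.agents}) != len(self.agents):
            raise TrialValidationError(f"trial {self.trial_id!r}: duplicate agents")
        if self.sample_size < 1:
            raise TrialValidationError(f"trial {self.trial_id!r}: sample_size must be >= 1")
        if not 0 <= self.n_responders <= self.sample_size:
            raise TrialValidationError(
                f"trial {self.trial_id!r}: n_responders={self.n_responders} "
                f"outside [0, {self.sample_size}]"
            )

    @property
    def combination(self) -> Combination:
        return Combination(self.agents)


class AgentRegistry:
    """Canonical agent names, synonyms, and the monoclonal-antibody flag.

    Lookup is case-insensitive and whitespace-tolerant. Names absent from
    the registry can be auto-registered (``strict=False``, the default),
    in which case the mAb flag falls back to the INN ``-mab`` suffix.
    """

    def __init__(self, strict: bool = False) -> None:
        self.strict = strict
        self._entries: "OrderedDict[str, dict]" = OrderedDict()
        self._lookup: dict[str, str] = {}

    def register(
        self,
        canonical: str,
        synonyms: Sequence[str] = (),
        is_monoclonal_antibody: bool | None = None,
    ) -> None:
        canonical = _canonical_key(canonical)
        self._entries[canonical] = {
            "synonyms": [_canonical_key(s) for s in synonyms],
            "is_monoclonal_antibody": is_monoclonal_antibody,
        }
        self._lookup[canonical] = canonical
        for s in synonyms:
            self._lookup[_canonical_key(s)] = canonical

    def resolve(self, name: str) -> str:
        key = _canonical_key(name)
        if not key:
            raise TrialValidationError("empty agent name")
        if key in self._lookup:
            return self._lookup[key]
        if self.strict:
            raise TrialValidationError(f"unresolvable agent name: {name!r}")
        self.register(key)
        return key

    def is_monoclonal(self, name: str) -> bool:
        canonical = self._lookup.get(_canonical_key(name))
        if canonical is None:
            if self.strict:
                raise TrialValidationError(f"unresolvable agent name: {name!r}")
            canonical = self.resolve(name)
        flag = self._entries[canonical]["is_monoclonal_antibody"]
        if flag is None:
            return canonical.endswith("mab")
        return bool(flag)

    def __contains__(self, name: str) -> bool:
        return _canonical_key(name) in self._lookup

    @classmethod
    def from_mapping(cls, entries: Mapping[str, Mapping], strict: bool = False) -> "AgentRegistry":
        reg = cls(strict=strict)
        for name, spec in entries.items():
            reg.register(
                name,
                synonyms=spec.get("synonyms", ()),
                is_monoclonal_antibody=spec.get("is_monoclonal_antibody"),
            )
        return reg


def flag_monoclonal(agent: str, registry: AgentRegistry) -> bool:
    """True when ``agent`` is a monoclonal antibody (registry flag, else ``-mab`` suffix)."""
    return registry.is_monoclonal(agent)


def _parse_agents_cell(cell: str, registry: AgentRegistry, trial_id: str) -> tuple[str, ...]:
    parts = [p for p in (s.strip() for s in str(cell).split(";")) if p]
    if not parts:
        raise TrialValidationError(f"trial {trial_id!r}: empty agents cell")
    return tuple(registry.resolve(p) for p in parts)


def read_trials(path: str | Path, registry: AgentRegistry | None = None) -> list[TrialRecord]:
    """Read a trials CSV into :class:`TrialRecord` objects, row order preserved."""
    if registry is None:
        registry = AgentRegistry()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"missing required column(s): {', '.join(missing)}")
    records: list[TrialRecord] = []
    for row in df.itertuples(index=False):
        trial_id = str(row.trial_id)
        try:
            n = int(row.n_responders)
            big_n = int(row.sample_size)
        except ValueError as exc:
            raise TrialValidationError(f"trial {trial_id!r}: non-integer counts") from exc
        year = None
        if "year" in df.columns:
            raw = getattr(row, "year", "")
            if str(raw).strip():
                year = int(float(raw))
        records.append(
            TrialRecord(
                trial_id=trial_id,
                agents=_parse_agents_cell(row.agents, registry, trial_id),
                n_responders=n,
                sample_size=big_n,
                cancer_type=str(row.cancer_type),
                year=year,
            )
        )
    return records


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = [
        {
            "trial_id": t.trial_id,
            "agents": ";".join(t.agents),
            "n_responders": t.n_responders,
            "sample_size": t.sample_size,
            "cancer_type": t.cancer_type,
            "year": "" if t.year is None else t.year,
        }
        for t in trials
    ]
    return pd.DataFrame(rows, columns=["trial_id", "agents", "n_responders", "sample_size", "cancer_type", "year"])


def write_trials(trials: Iterable[TrialRecord], path: str | Path) -> None:
    """Write trials as CSV (round-trips with :func:`read_trials`)."""
    trials_to_frame(trials).to_csv(path, index=False)


def write_catalog(results, path: str | Path) -> None:
    """Write an interaction catalog as TSV (one row per agent pair).

    Columns mirror the published synergy/antagonism tables: the pair, the
    expected ORR under non-interaction, the observed pooled ORR, both tail
    p-values and the assigned label, plus the pooled counts behind them.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "agent_1": r.pair.agents[0],
                "agent_2": r.pair.agents[1],
                "expected_ORR1": round(r.orr1) if r.orr1 is not None else "",
                "observed_ORR0": round(r.orr0) if r.orr0 is not None else "",
                "p_synergy": r.p_synergy,
                "p_antagonism": r.p_antagonism,
                "label": r.label,
                "n_pooled": r.n_pooled,
                "N_pooled": r.N_pooled,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "agent_1", "agent_2", "expected_ORR1", "observed_ORR0",
            "p_synergy", "p_antagonism", "label", "n_pooled", "N_pooled",
        ],
    ).to_csv(path, sep="\t", index=False)


def group_by_combination(trials: Iterable[TrialRecord]) -> dict[Combination, list[TrialRecord]]:
    """Group trials by the (order-insensitive) combination they tested."""
    groups: dict[Combination, list[TrialRecord]] = {}
    for t in trials:
        groups.setdefault(t.combination, []).append(t)
    return groups


def write_model_json(payload: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
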