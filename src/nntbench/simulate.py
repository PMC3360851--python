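"""Synthetic two-arm binary-outcome trials.

Each arm's event count is an independent binomial draw at a known true
event probability, which is exactly the sampling model implicit in a
per-arm event-percentage table.  A panel of named scenarios emulates a
multi-endpoint trial ledger (several endpoints measured on the same arms);
endpoints are generated independently — within-patient correlation between
endpoints is deliberately out of scope.

Determinism: one top-level seed, with per-scenario substreams derived as
``seed + index`` so appending scenarios to a panel never perturbs the rows
already generated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import yaml

from .tables import TwoByTwoTable
from .trials import EndpointRow

__all__ = [
    "TrialScenario",
    "simulate_trial",
    "simulate_endpoint_panel",
    "load_scenarios",
    "panel_to_csv",
]


@dataclass(frozen=True)
class TrialScenario:
    """True parameters of a synthetic two-arm trial.

    p_exp, p_ctrl : true event probabilities per arm, in [0, 1]
    n_exp, n_ctrl : arm sizes (>= 1)
    seed : RNG seed; identical (scenario, seed) gives identical output
    name, endpoint_class : panel metadata, passed through to EndpointRow
    """

    p_exp: float
    p_ctrl: float
    n_exp: int
    n_ctrl: int
    seed: int = 0
    name: str = "endpoint"
    endpoint_class: str = "efficacy"

    def __post_init__(self) -> None:
        for nm in ("p_exp", "p_ctrl"):
            p = getattr(self, nm)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{nm} must be in [0, 1], got {p!r}")
        for nm in ("n_exp", "n_ctrl"):
            v = getattr(self, nm)
            if not isinstance(v, int) or v < 1:
                raise ValueError(f"{nm} must be an integer >= 1, got {v!r}")

    @property
    def true_arr(self) -> float:
        """True absolute risk reduction, control minus experimental."""
        return self.p_ctrl - self.p_exp


def simulate_trial(s: TrialScenario) -> TwoByTwoTable:
    """Draw one synthetic trial: a ~ Bin(n_exp, p_exp), c ~ Bin(n_ctrl,
    p_ctrl), independent, deterministic under the scenario's seed."""
    rng = np.random.default_rng(s.seed)
    a = int(rng.binomial(s.n_exp, s.p_exp))
    c = int(rng.binomial(s.n_ctrl, s.p_ctrl))
    return TwoByTwoTable(a, s.n_exp - a, c, s.n_ctrl - c)


def simulate_endpoint_panel(
    config: Sequence[TrialScenario], seed: Optional[int] = None
) -> List[EndpointRow]:
    """Simulate one EndpointRow per scenario with observed (not true) rates.

    Scenario i uses substream seed + i (the panel seed overrides any seeds
    stored on the scenarios).  Duplicate endpoint names are rejected.
    """
    if not config:
        raise ValueError("empty panel config")
    names = [s.name for s in config]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate endpoint names in panel: {dupes}")
    base = config[0].seed if seed is None else seed
    rows = []
    for i, s in enumerate(config):
        t = simulate_trial(replace(s, seed=base + i))
        rows.append(EndpointRow(
            trial="synthetic",
            endpoint=s.name,
            endpoint_class=s.endpoint_class,  # type: ignore[arg-type]
            exp_rate=Fraction(t.a, t.n),
            ctrl_rate=Fraction(t.c, t.m),
            exp_n=t.n,
            ctrl_n=t.m,
        ))
    return rows


def load_scenarios(path) -> List[TrialScenario]:
    """Read a panel config: a YAML list of blocks with keys name, p_exp,
    p_ctrl, n_exp, n_ctrl and optional endpoint_class, seed."""
    with open(Path(path)) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError("scenario config must be a YAML list of mappings")
    out = []
    for i, block in enumerate(raw):
        try:
            out.append(TrialScenario(
                p_exp=float(block["p_exp"]),
                p_ctrl=float(block["p_ctrl"]),
                n_exp=int(block["n_exp"]),
                n_ctrl=int(block["n_ctrl"]),
                seed=int(block.get("seed", 0)),
                name=str(block.get("name", f"endpoint_{i}")),
                endpoint_class=str(block.get("endpoint_class", "efficacy")),
            ))
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"scenario block {i}: {exc}") from exc
    return out


def panel_to_csv(rows: Sequence[EndpointRow]) -> str:
    """Serialize a panel in the endpoint CSV schema consumed by
    :func:`nntbench.trials.load_endpoints`."""
    import csv as _csv
    import io as _io

    buf = _io.StringIO()
    writer = _csv.writer(buf)
    writer.writerow([
        "trial", "endpoint", "endpoint_class",
        "exp_rate_pct", "ctrl_rate_pct", "exp_n", "ctrl_n", "printed_value",
    ])
    for r in rows:
        writer.writerow([
            r.trial, r.endpoint, r.endpoint_class,
            f"{float(r.exp_rate) * 100:.6f}", f"{float(r.ctrl_rate) * 100:.6f}",
            r.exp_n, r.ctrl_n, "",
        ])
    return buf.getvalue()
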