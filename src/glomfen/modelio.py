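"""Readers/writers for the tabular network model and pipeline artifacts.

The network ships as two tab-separated tables:

``species.tsv``  columns: id, ymax, y0, tau, tau_class, compartment, provenance
``reactions.tsv`` columns: id, rule, W, n, EC50

Rules use the Netflux-style grammar ``[!]ID ( & [!]ID )* => ID`` where ``!``
marks an inhibiting input and ``&`` an AND gate; multiple rows with the same
target combine by OR.  The bare rule ``=> ID`` declares the external stimulus.
"""

from __future__ import annotations

import hashlib
import json
import re
from importlib import resources
from pathlib import Path

import pandas as pd

from .glucose import GlucoseSchedule
from .network import ReactionSpec, SpeciesSpec, NetworkSpec

__all__ = [
    "parse_rule",
    "format_rule",
    "read_model",
    "write_model",
    "default_model",
    "read_glucose_fixture",
    "write_glucose_fixture",
    "read_observations",
    "write_observations",
    "write_results",
    "config_hash",
]

_IDENT = r"[A-Za-z_][A-Za-z0-9_]*"
_RULE_RE = re.compile(
    rf"^\s*(?P<lhs>(!?\s*{_IDENT}\s*)(&\s*!?\s*{_IDENT}\s*)*)?=>\s*(?P<rhs>{_IDENT})\s*$"
)


class RuleSyntaxError(ValueError):
    pass


def parse_rule(rule: str) -> tuple[tuple[tuple[str, str], ...], str, str]:
    """Parse a rule string into (inputs, gate, target).

    Returns inputs as ((species, 'activating'|'inhibiting'), ...); gate is
    'SINGLE', 'AND', or 'STIMULUS' for an empty left-hand side.
    """
    m = _RULE_RE.match(rule)
    if m is None:
        arrow = rule.find("=>")
        raise RuleSyntaxError(
            f"cannot parse rule {rule!r}"
            + (f" (near position {arrow})" if arrow >= 0 else " (missing '=>')")
        )
    target = m.group("rhs")
    lhs = m.group("lhs")
    if lhs is None or not lhs.strip():
        return (), "STIMULUS", target
    inputs = []
    for term in lhs.split("&"):
        term = term.strip()
        if term.startswith("!"):
            inputs.append((term[1:].strip(), "inhibiting"))
        else:
            inputs.append((term, "activating"))
    gate = "AND" if len(inputs) > 1 else "SINGLE"
    return tuple(inputs), gate, target


def format_rule(inputs, target: str) -> str:
    if not inputs:
        return f"=> {target}"
    lhs = " & ".join(
        ("!" if sign == "inhibiting" else "") + src for src, sign in inputs
    )
    return f"{lhs} => {target}"


def read_model(
    species_path, reactions_path, variant: str = "disease"
) -> NetworkSpec:
    sp = pd.read_csv(species_path, sep="\t", comment="#")
    rx = pd.read_csv(reactions_path, sep="\t", comment="#")
    for col in ("id", "ymax", "y0", "tau", "tau_class", "compartment"):
        if col not in sp.columns:
            raise ValueError(f"species table missing column {col!r}")
    for col in ("id", "rule", "W", "n", "EC50"):
        if col not in rx.columns:
            raise ValueError(f"reaction table missing column {col!r}")
    species = [
        SpeciesSpec(
            id=str(row.id),
            ymax=float(row.ymax),
            y0=float(row.y0),
            tau=float(row.tau),
            tau_class=str(row.tau_class),
            compartment=str(row.compartment),
            provenance=str(getattr(row, "provenance", "default")),
        )
        for row in sp.itertuples(index=False)
    ]
    reactions = []
    for row in rx.itertuples(index=False):
        inputs, _, target = parse_rule(str(row.rule))
        reactions.append(
            ReactionSpec(
                id=int(row.id),
                inputs=inputs,
                target=target,
                W=float(row.W),
                n=float(row.n),
                ec50=float(row.EC50),
            )
        )
    return NetworkSpec(species=species, reactions=reactions).with_variant(variant)


def write_model(spec: NetworkSpec, species_path, reactions_path) -> None:
    pd.DataFrame(
        [
            {
                "id": s.id,
                "ymax": s.ymax,
                "y0": s.y0,
                "tau": s.tau,
                "tau_class": s.tau_class,
                "compartment": s.compartment,
                "provenance": s.provenance,
            }
            for s in spec.species
        ]
    ).to_csv(species_path, sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "id": r.id,
                "rule": format_rule(r.inputs, r.target),
                "W": r.W,
                "n": r.n,
                "EC50": r.ec50,
            }
            for r in spec.reactions
        ]
    ).to_csv(reactions_path, sep="\t", index=False)


def _data(name: str):
    return resources.files("glomfen").joinpath("data", name)


def default_model(variant: str = "disease") -> NetworkSpec:
    """The packaged 34-species macrophage-GEC network."""
    with resources.as_file(_data("species.tsv")) as sp, resources.as_file(
        _data("reactions.tsv")
    ) as rx:
        return read_model(sp, rx, variant=variant)


def read_glucose_fixture(csv_path, header_path) -> GlucoseSchedule:
    header = json.loads(Path(header_path).read_text())
    tab = pd.read_csv(csv_path, comment="#")
    intervals = tuple(
        (float(r.t_start_h), float(r.t_end_h), float(r.mean_mmol_l))
        for r in tab.itertuples(index=False)
    )
    return GlucoseSchedule(
        intervals=intervals,
        gmax=float(header["gmax_mmol_l"]),
        slope=float(header.get("slope", 0.051)),
        intercept=float(header.get("intercept", -9.38)),
    )


def read_glucose_stats(csv_path) -> list[tuple[float, float, float, float]]:
    tab = pd.read_csv(csv_path, comment="#")
    return [
        (float(r.t_start_h), float(r.t_end_h), float(r.mean_mmol_l), float(r.sd_mmol_l))
        for r in tab.itertuples(index=False)
    ]


def write_glucose_fixture(stats, header: dict, csv_path, header_path) -> None:
    pd.DataFrame(
        stats, columns=["t_start_h", "t_end_h", "mean_mmol_l", "sd_mmol_l"]
    ).to_csv(csv_path, index=False)
    Path(header_path).write_text(json.dumps(header, indent=1))


def default_glucose() -> tuple[GlucoseSchedule, list[tuple[float, float, float, float]]]:
    """Packaged mean glucose schedule plus its interval (mean, SD) statistics."""
    with resources.as_file(_data("glucose_intervals.csv")) as csv, resources.as_file(
        _data("glucose_header.json")
    ) as hdr:
        sched = read_glucose_fixture(csv, hdr)
        stats = read_glucose_stats(csv)
    return sched, stats


def default_structure_params():
    from .structure import FenestrationParams

    return FenestrationParams.from_json(_data("fenestration_params.json").read_text())


def read_observations(path) -> pd.DataFrame:
    obs = pd.read_csv(path, comment="#")
    need = {"week", "arm", "quantity", "mean", "sd"}
    if not need.issubset(obs.columns):
        raise ValueError(f"observations table needs columns {sorted(need)}")
    return obs.sort_values(["arm", "quantity", "week"]).reset_index(drop=True)


def write_observations(obs: pd.DataFrame, path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        if meta:
            fh.write("# " + json.dumps(meta) + "\n")
        obs.to_csv(fh, index=False)


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_results(objects: dict, out_dir, seed: int | None = None, config=None) -> list[Path]:
    """Write a dict of named results (DataFrames -> CSV, dict/list -> JSON).

    Every file records the seed and configuration hash in a leading comment
    (CSV) or embedded meta entry (JSON).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": seed, "config_hash": config_hash(config) if config else None}
    written = []
    for name, obj in objects.items():
        if isinstance(obj, pd.DataFrame):
            path = out / f"{name}.csv"
            with open(path, "w") as fh:
                fh.write("# " + json.dumps(meta) + "\n")
                obj.to_csv(fh, index=False)
        else:
            path = out / f"{name}.json"
            path.write_text(json.dumps({"meta": meta, name: obj}, indent=1, default=str))
        written.append(path)
    return written
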