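"""Serialization: tidy time-series tables and the declarative network format.

All traces, profiles and targets interchange as UTF-8 tab-separated text
with a header row whose first column is ``time_s``.  Reaction networks
serialize to a three-section declarative format::

    # species
    C1_0 10.0

    # reactions
    C1_0 + C2_1 -> C3_0 ; k=0.35
    g3p -> pep ; law=michaelis_menten vmax=60 km=5

    # inputs
    dha -> C3_0
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .metabolic import MetabolicModel, MetReaction
from .reservoir import CRNSpec, Reaction


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# tidy time-series tables

def write_timeseries(table: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy table (``time_s`` first, numeric columns) as TSV."""
    if table.columns[0] != "time_s":
        raise FormatError("first column must be 'time_s'")
    table.to_csv(path, sep="\t", index=False)


def read_timeseries(path: str | Path) -> pd.DataFrame:
    """Read a tidy TSV table, enforcing the time-series contract.

    Requires a ``time_s`` first column, fully numeric values, no ragged
    rows, and strictly increasing time; violations raise
    :class:`FormatError` with the offending row where applicable.
    """
    try:
        table = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed rows ({exc})") from exc
    if table.columns[0] != "time_s":
        raise FormatError(f"{path}: first column must be 'time_s'")
    for col in table.columns:
        if not np.issubdtype(table[col].dtype, np.number):
            raise FormatError(f"{path}: column {col!r} is not numeric")
    if table.isna().any().any():
        row = int(table.isna().any(axis=1).idxmax())
        raise FormatError(f"{path}: missing value at data row {row}")
    dt = np.diff(table["time_s"].to_numpy())
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 1
        raise FormatError(f"{path}: time not strictly increasing at data row {row}")
    return table


# ---------------------------------------------------------------------------
# declarative reaction-network format

def _format_side(pairs) -> str:
    terms = [(f"{int(c)} {s}" if c != 1 else s) for s, c in pairs]
    return " + ".join(terms) if terms else "0"


def _parse_side(text: str) -> tuple[tuple[str, int], ...]:
    text = text.strip()
    if text == "0" or not text:
        return ()
    out = []
    for term in text.split("+"):
        parts = term.split()
        if len(parts) == 1:
            out.append((parts[0], 1))
        elif len(parts) == 2:
            out.append((parts[1], int(parts[0])))
        else:
            raise FormatError(f"cannot parse reaction term {term!r}")
    return tuple(out)


def write_network(spec: CRNSpec | MetabolicModel, path: str | Path) -> None:
    path = Path(path)
    lines = ["# species"]
    if isinstance(spec, CRNSpec):
        for s in spec.species:
            size = spec.sizes.get(s)
            lines.append(f"{s} 0.0" + (f" size={size}" if size else ""))
        lines.append("")
        lines.append("# reactions")
        for rxn in spec.reactions:
            lines.append(rxn.format())
        lines.append("")
        lines.append("# inputs")
        for channel, target in spec.input_map.items():
            lines.append(f"{channel} -> {target}")
    else:
        for s in spec.substrates:
            lines.append(f"{s} {spec.initial_concentrations.get(s, 0.0):g}")
        lines.append("")
        lines.append("# reactions")
        for rxn in spec.reactions:
            head = f"{_format_side(rxn.reactants)} -> {_format_side(rxn.products)}"
            if rxn.law == "mass_action":
                lines.append(f"{head} ; k={rxn.k:g}")
            else:
                lines.append(f"{head} ; law={rxn.law} vmax={rxn.vmax:g} km={rxn.km:g}")
        lines.append("")
        lines.append("# inputs")
        if spec.driven:
            lines.append(f"driven -> {spec.driven}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_network(path: str | Path, kind: str = "crn") -> CRNSpec | MetabolicModel:
    """Parse the declarative format back into a network object.

    ``kind`` selects the container: ``"crn"`` (reservoir network) or
    ``"metabolic"`` (kinetic target model).
    """
    path = Path(path)
    section = None
    species: list[str] = []
    initial: dict[str, float] = {}
    sizes: dict[str, int] = {}
    reactions_raw: list[tuple] = []
    inputs: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            section = line.lstrip("# ").lower()
            continue
        if section == "species":
            parts = line.split()
            species.append(parts[0])
            if len(parts) > 1:
                initial[parts[0]] = float(parts[1])
            for extra in parts[2:]:
                if extra.startswith("size="):
                    sizes[parts[0]] = int(extra[5:])
        elif section == "reactions":
            if ";" not in line:
                raise FormatError(f"{path}:{lineno}: reaction missing parameters")
            eqn, params_text = line.split(";", 1)
            if "->" not in eqn:
                raise FormatError(f"{path}:{lineno}: reaction missing '->'")
            lhs, rhs = eqn.split("->")
            params = dict(
                item.split("=", 1) for item in params_text.split() if "=" in item
            )
            reactions_raw.append((_parse_side(lhs), _parse_side(rhs), params, lineno))
        elif section == "inputs":
            if "->" not in line:
                raise FormatError(f"{path}:{lineno}: input mapping missing '->'")
            channel, target = (part.strip() for part in line.split("->"))
            inputs[channel] = target
        else:
            raise FormatError(f"{path}:{lineno}: content outside a known section")
    if kind == "crn":
        reactions = [
            Reaction(lhs, rhs, float(params["k"]))
            for lhs, rhs, params, _ in reactions_raw
        ]
        return CRNSpec(
            species=species, reactions=reactions, input_map=inputs, sizes=sizes
        )
    if kind == "metabolic":
        reactions = []
        for i, (lhs, rhs, params, lineno) in enumerate(reactions_raw):
            law = params.get("law", "mass_action")
            if law == "mass_action":
                reactions.append(
                    MetReaction(f"r{i}", lhs, rhs, law=law, k=float(params["k"]))
                )
            else:
                reactions.append(
                    MetReaction(
                        f"r{i}", lhs, rhs, law=law,
                        vmax=float(params["vmax"]), km=float(params["km"]),
                    )
                )
        return MetabolicModel(
            substrates=species,
            reactions=reactions,
            initial_concentrations=initial,
            driven=inputs.get("driven"),
        )
    raise FormatError(f"unknown network kind {kind!r}")
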