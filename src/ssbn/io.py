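"""File formats: cohort CSV + variable metadata, network JSON and XMLBIF.

The CSV dialect is comma-separated UTF-8 with a header row; the empty
string marks a missing cell.  Numeric raw columns with declared cut-points
are discretised into half-open bins [low, high), the last bin closed above.

Network JSON schema::

    {"variables": [{"name": ..., "states": [...], "role": ...}, ...],
     "arcs": [[parent, child], ...],
     "cpts": [{"child": ..., "parents": [...], "table": [[...], ...]}, ...]}

XMLBIF export/import is provided for interoperability with other Bayesian
network tools; the target role is carried in a variable PROPERTY.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

from .datatable import DataTable
from .exceptions import ConfigurationError, ValidationError
from .network import (
    BayesianNetwork,
    ConditionalProbabilityTable,
    DiscreteVariable,
    NetworkStructure,
)


@dataclass
class VariableMetadata:
    """Codebook entry for one column."""

    name: str
    states: list[str]
    role: str = "feature"
    cutpoints: list[float] | None = None

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise ValidationError(f"duplicate states for {self.name!r}")
        if self.cutpoints is not None:
            if sorted(self.cutpoints) != list(self.cutpoints) or len(
                set(self.cutpoints)
            ) != len(self.cutpoints):
                raise ValidationError(
                    f"cut-points for {self.name!r} must be strictly increasing"
                )
            if len(self.states) != len(self.cutpoints) + 1:
                raise ValidationError(
                    f"{self.name!r}: need one state label per bin "
                    f"({len(self.cutpoints) + 1}), got {len(self.states)}"
                )

    def to_variable(self) -> DiscreteVariable:
        return DiscreteVariable(self.name, tuple(self.states), self.role)


def read_metadata(path) -> list[VariableMetadata]:
    with open(path) as fh:
        raw = json.load(fh)
    entries = [VariableMetadata(**item) for item in raw["variables"]]
    targets = [e.name for e in entries if e.role == "target"]
    if len(targets) != 1:
        raise ConfigurationError(
            f"metadata must declare exactly one target (found {targets})"
        )
    return entries


def write_metadata(entries: list[VariableMetadata], path) -> None:
    payload = {
        "variables": [
            {
                "name": e.name,
                "states": list(e.states),
                "role": e.role,
                **({"cutpoints": list(e.cutpoints)} if e.cutpoints else {}),
            }
            for e in entries
        ]
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_cohort(csv_path, metadata_path) -> DataTable:
    """Load and validate a cohort CSV against its metadata codebook."""
    entries = read_metadata(metadata_path)
    raw = pd.read_csv(csv_path, dtype=str, keep_default_na=False)
    missing_meta = [c for c in raw.columns if c not in {e.name for e in entries}]
    if missing_meta:
        raise ConfigurationError(f"no metadata for columns {missing_meta}")
    absent = [e.name for e in entries if e.name not in raw.columns]
    if absent:
        raise ConfigurationError(f"CSV lacks declared columns {absent}")
    cols = {}
    for e in entries:
        col = raw[e.name]
        if e.cutpoints:
            cols[e.name] = _discretize(col, e)
        else:
            cols[e.name] = col
    frame = pd.DataFrame(cols)[[e.name for e in entries]]
    return DataTable.from_strings([e.to_variable() for e in entries], frame)


def _discretize(col: pd.Series, meta: VariableMetadata) -> pd.Series:
    out = []
    for i, cell in enumerate(col):
        if cell == "" or cell is None:
            out.append(None)
            continue
        try:
            value = float(cell)
        except ValueError:
            raise ValidationError(
                f"non-numeric cell {cell!r} for cut-point column "
                f"{meta.name!r} at row {i}"
            ) from None
        bin_idx = int(np.digitize(value, meta.cutpoints, right=False))
        out.append(meta.states[bin_idx])
    return pd.Series(out, index=col.index, dtype=object)


# ---------------------------------------------------------------------------
# network JSON


def network_to_dict(net: BayesianNetwork) -> dict:
    return {
        "variables": [
            {"name": v.name, "states": list(v.states), "role": v.role}
            for v in net.variables.values()
        ],
        "arcs": [list(a) for a in net.structure.arcs],
        "cpts": [
            {
                "child": name,
                "parents": list(cpt.parents),
                "table": cpt.table.tolist(),
            }
            for name, cpt in net.cpts.items()
        ],
    }


def network_from_dict(payload: dict) -> BayesianNetwork:
    try:
        variables = [
            DiscreteVariable(v["name"], tuple(v["states"]), v.get("role", "feature"))
            for v in payload["variables"]
        ]
        structure = NetworkStructure(variables, [tuple(a) for a in payload["arcs"]])
        cpts = {}
        for item in payload["cpts"]:
            child = item["child"]
            parents = tuple(item["parents"])
            cards = [structure.variables[p].cardinality for p in parents]
            cpts[child] = ConditionalProbabilityTable(
                child, parents, item["table"], cards,
                structure.variables[child].cardinality,
            )
        return BayesianNetwork(structure, cpts)
    except KeyError as err:
        raise ValidationError(f"malformed network payload: missing {err}") from None


def write_network_json(net: BayesianNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(net), fh, indent=1)


def read_network_json(path) -> BayesianNetwork:
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as err:
            raise ValidationError(f"{path}: invalid JSON at line {err.lineno}") from None
    return network_from_dict(payload)


# ---------------------------------------------------------------------------
# XMLBIF


def write_network_xmlbif(net: BayesianNetwork, path, name: str = "network") -> None:
    bif = ET.Element("BIF", VERSION="0.3")
    nw = ET.SubElement(bif, "NETWORK")
    ET.SubElement(nw, "NAME").text = name
    for v in net.variables.values():
        var = ET.SubElement(nw, "VARIABLE", TYPE="nature")
        ET.SubElement(var, "NAME").text = v.name
        for s in v.states:
            ET.SubElement(var, "OUTCOME").text = s
        if v.role == "target":
            ET.SubElement(var, "PROPERTY").text = "role = target"
    for child, cpt in net.cpts.items():
        d = ET.SubElement(nw, "DEFINITION")
        ET.SubElement(d, "FOR").text = child
        for p in cpt.parents:
            ET.SubElement(d, "GIVEN").text = p
        # row-major: parent configurations in odometer order (last parent
        # fastest), child states fastest of all — the XMLBIF convention
        ET.SubElement(d, "TABLE").text = " ".join(
            repr(float(x)) for x in cpt.table.ravel()
        )
    ET.indent(bif)
    ET.ElementTree(bif).write(path, encoding="unicode", xml_declaration=True)


def read_network_xmlbif(path) -> BayesianNetwork:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as err:
        raise ValidationError(f"{path}: malformed XML ({err})") from None
    nw = root.find("NETWORK")
    if nw is None:
        raise ValidationError(f"{path}: no NETWORK element")
    variables = []
    for var in nw.findall("VARIABLE"):
        vname = var.findtext("NAME")
        states = tuple(o.text for o in var.findall("OUTCOME"))
        role = "feature"
        for prop in var.findall("PROPERTY"):
            if prop.text and prop.text.replace(" ", "") == "role=target":
                role = "target"
        variables.append(DiscreteVariable(vname, states, role))
    by_name = {v.name: v for v in variables}
    arcs = []
    defs = []
    for d in nw.findall("DEFINITION"):
        child = d.findtext("FOR")
        parents = tuple(g.text for g in d.findall("GIVEN"))
        table = np.array([float(x) for x in d.findtext("TABLE").split()])
        defs.append((child, parents, table))
        arcs.extend((p, child) for p in parents)
    structure = NetworkStructure(variables, arcs)
    cpts = {}
    for child, parents, flat in defs:
        cards = [by_name[p].cardinality for p in parents]
        child_card = by_name[child].cardinality
        n_cfg = int(np.prod(cards)) if parents else 1
        cpts[child] = ConditionalProbabilityTable(
            child, parents, flat.reshape(n_cfg, child_card), cards, child_card
        )
    return BayesianNetwork(structure, cpts)


def write_network(net: BayesianNetwork, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".xml", ".xmlbif", ".bif"):
        write_network_xmlbif(net, path)
    else:
        write_network_json(net, path)


def read_network(path) -> BayesianNetwork:
    path = Path(path)
    if path.suffix.lower() in (".xml", ".xmlbif", ".bif"):
        return read_network_xmlbif(path)
    return read_network_json(path)
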