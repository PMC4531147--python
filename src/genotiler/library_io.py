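"""Component-library documents (XML primary, JSON alternative) and the
built-in worked-example fixtures.

The XML dialect validates against the shipped XSD::

    <library schema="genotiler-library/1">
      <component name="Q1"><program>LacI o-&gt; !TetR_lite</program></component>
      ...
    </library>

The JSON dialect mirrors it (a JSON-Schema file documents it; validation is
performed by the loader itself).  Each component's behaviour is embedded as
DSL text and parsed, macro-expanded and validated on load.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Tuple

from lxml import etree

from .errors import LibraryFormatError, ParseError, ValidationError
from .lang import Program
from .matching import Component, ComponentLibrary
from .parser import parse_program, serialize_program
from .semantics import ChronologicalDivision, Trace, parse_trace

SCHEMA_ID = "genotiler-library/1"


def _xsd() -> etree.XMLSchema:
    text = resources.files("genotiler.schemas").joinpath("library.xsd").read_text()
    return etree.XMLSchema(etree.fromstring(text.encode()))


def _component(name: str, text: str, where: str) -> Component:
    try:
        return Component(name, parse_program(text))
    except (ParseError, ValidationError) as e:
        raise LibraryFormatError(f"component {name!r} in {where}: {e}") from e


def read_library(path, fmt: Optional[str] = None) -> ComponentLibrary:
    """Load and validate a library file; ``fmt`` in {"xml", "json"} or
    inferred from the extension."""
    path = Path(path)
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "xml")
    raw = path.read_text()
    if fmt == "xml":
        try:
            root = etree.fromstring(raw.encode())
        except etree.XMLSyntaxError as e:
            raise LibraryFormatError(f"{path}: not well-formed XML: {e}") from e
        xsd = _xsd()
        if not xsd.validate(root):
            err = xsd.error_log[0]
            raise LibraryFormatError(f"{path}: schema violation at line {err.line}: {err.message}")
        comps = [_component(el.get("name"), el.findtext("program") or "", str(path))
                 for el in root.findall("component")]
    elif fmt == "json":
        try:
            doc = json.loads(raw)
        except json.JSONDecodeError as e:
            raise LibraryFormatError(f"{path}: invalid JSON: {e}") from e
        _validate_json_doc(doc, str(path))
        comps = [_component(c["name"], c["program"], str(path))
                 for c in doc["components"]]
    else:
        raise ValueError(f"unknown library format {fmt!r}")
    try:
        return ComponentLibrary(tuple(comps), source=str(path))
    except ValidationError as e:
        raise LibraryFormatError(f"{path}: {e}") from e


def _validate_json_doc(doc, where: str) -> None:
    if not isinstance(doc, dict) or doc.get("schema") != SCHEMA_ID:
        raise LibraryFormatError(f"{where}: expected object with schema={SCHEMA_ID!r}")
    comps = doc.get("components")
    if not isinstance(comps, list):
        raise LibraryFormatError(f"{where}: 'components' must be a list")
    for i, c in enumerate(comps):
        if not isinstance(c, dict) or not isinstance(c.get("name"), str) or not c.get("name"):
            raise LibraryFormatError(f"{where}: components[{i}] needs a non-empty 'name'")
        if not isinstance(c.get("program"), str):
            raise LibraryFormatError(f"{where}: components[{i}] needs a 'program' string")
        extra = set(c) - {"name", "program", "description"}
        if extra:
            raise LibraryFormatError(f"{where}: components[{i}] has unknown keys {sorted(extra)}")


def write_library(lib: ComponentLibrary, path, fmt: Optional[str] = None) -> Path:
    """Serialize a library; ``read_library`` of the result is structurally
    equal to ``lib``."""
    path = Path(path)
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "xml")
    if fmt == "xml":
        root = etree.Element("library", schema=SCHEMA_ID)
        for c in lib:
            el = etree.SubElement(root, "component", name=c.name)
            etree.SubElement(el, "program").text = "\n" + serialize_program(c.program)
        path.write_bytes(etree.tostring(root, pretty_print=True,
                                        xml_declaration=True, encoding="UTF-8"))
    elif fmt == "json":
        doc = {"schema": SCHEMA_ID,
               "components": [{"name": c.name, "program": serialize_program(c.program)}
                              for c in lib]}
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        raise ValueError(f"unknown library format {fmt!r}")
    return path


# --------------------------------------------------------------------------- #
# worked-example fixtures

REPRESSILATOR_GOAL_SRC = """\
# three-gene mutual-inhibition ring; g1, g2 abstract two of the genes
g1 o-> !g2
g2 o-> !TetR_lite
TetR_lite o-> !g1
"""

# A five-entry slice of a part catalogue consistent with the worked
# compilation of the ring: Q1..Q3 are the canonical LacI/TetR/CI repressor
# cascade, Q4 a TetR-driven reporter knock-down, Q5 an unrelated AraC-driven
# knock-down.  Q4/Q5 are synthetic reconstructions (the original catalogue
# figure is not machine-readable); what matters, and what the tests assert,
# is the association/elimination pattern they induce, not the part names.
REPRESSILATOR_LIB5 = (
    ("Q1", "LacI o-> !TetR_lite"),
    ("Q2", "CI o-> !LacI"),
    ("Q3", "TetR_lite o-> !CI"),
    ("Q4", "TetR_lite o-> !GFP"),
    ("Q5", "AraC o-> !GFP"),
)

LAMBDA_SWITCH_SRC = """\
# lysis/lysogeny switch of phage lambda: Cro and CI mutually inhibiting
Cro:{low<high}
CI:{low<high}
Cro(low) -- CI(high)
CI(low) -- Cro(high)
obs_1:: Cro(high)
obs_2:: Cro(low)
obs_3:: CI(low)
"""

EQ1_TRACE_SRC = """\
G(Low)
G(Low)
G(Mid)
G(Mid)
G(Mid)
G(High)
"""

EQ1_DIVISION = ((1, 2), (3, 5), (6, 6))


def fixtures() -> dict:
    """The in-package worked examples.

    ``repressilator_goal``  three persistent inhibitions over g1/g2/TetR_lite.
    ``repressilator_lib5``  the five-component catalogue slice above.
    ``lambda_switch``       the Cro/CI switch with attribute chains, two
                            strong-inhibition macros and three observation
                            spots.
    ``eq1_trace`` / ``eq1_division``  the six-instant Low->Mid->High trace and
                            its three-period chronological division.
    """
    return {
        "repressilator_goal": parse_program(REPRESSILATOR_GOAL_SRC),
        "repressilator_lib5": ComponentLibrary(
            tuple(Component(n, parse_program(src)) for n, src in REPRESSILATOR_LIB5),
            source="<builtin>"),
        "lambda_switch": parse_program(LAMBDA_SWITCH_SRC),
        "eq1_trace": parse_trace(EQ1_TRACE_SRC),
        "eq1_division": ChronologicalDivision(EQ1_DIVISION),
    }
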