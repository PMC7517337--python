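"""Plain-text I/O: symbol sequences, machine JSON, GraphViz export.

Sequence files hold one line of whitespace-free symbols, optionally
preceded by a header line ``# alphabet: 0 1``; without a header the
alphabet is inferred from the distinct symbols present (sorted), with a
warning logged.

Machine JSON schema::

    {"alphabet": [...], "states": [...],
     "transitions": {state: {symbol: {"p": float, "to": state}}}}

Serialization follows the states list order, so output is reproducible.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .machines import Alphabet, EpsilonMachine, SymbolSequence, validate_machine

__all__ = ["read_sequence", "write_sequence", "serialize_machine", "load_machine", "machine_to_dot"]

log = logging.getLogger("cmboot")


def write_sequence(seq: SymbolSequence, path) -> None:
    with open(path, "w") as fh:
        fh.write("# alphabet: " + " ".join(seq.alphabet.symbols) + "\n")
        fh.write("".join(seq.tokens()) + "\n")


def read_sequence(path, alphabet: Alphabet | None = None) -> SymbolSequence:
    """Read a sequence file; header alphabet wins, else inferred (logged)."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = [ln for ln in lines if ln.startswith("#")]
    body = [ln for ln in lines if not ln.startswith("#")]
    if not body:
        raise ValueError(f"empty sequence file: {path}")
    data = "".join(body)
    declared = None
    for ln in header:
        if ln.lower().lstrip("# ").startswith("alphabet:"):
            declared = Alphabet(tuple(ln.split(":", 1)[1].split()))
    if alphabet is None:
        alphabet = declared
    if alphabet is None:
        alphabet = Alphabet(tuple(sorted(set(data))))
        log.warning("no alphabet declared in %s; inferred %s", path, alphabet.symbols)
    return SymbolSequence(alphabet, list(data))


def serialize_machine(m: EpsilonMachine, path) -> None:
    trans: dict = {}
    for i, s in enumerate(m.states):
        trans[s] = {}
        for x, sym in enumerate(m.alphabet.symbols):
            if m.emit[i, x] > 0:
                trans[s][sym] = {"p": float(m.emit[i, x]), "to": m.states[int(m.next[i, x])]}
    obj = {"alphabet": list(m.alphabet.symbols), "states": list(m.states), "transitions": trans}
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
        fh.write("\n")


def load_machine(path) -> EpsilonMachine:
    """Load and validate a machine; refuses invalid machines with a report."""
    with open(path) as fh:
        obj = json.load(fh)
    for key in ("alphabet", "states", "transitions"):
        if key not in obj:
            raise ValueError(f"machine JSON missing key '$.{key}'")
    alphabet = Alphabet(tuple(obj["alphabet"]))
    states = [str(s) for s in obj["states"]]
    sidx = {s: i for i, s in enumerate(states)}
    k = len(alphabet)
    emit = np.zeros((len(states), k))
    nxt = np.full((len(states), k), -1, dtype=np.int64)
    for s, row in obj["transitions"].items():
        if s not in sidx:
            raise ValueError(f"unknown state at $.transitions.{s}")
        for sym, edge in row.items():
            x = alphabet.index(sym)
            if edge["to"] not in sidx:
                raise ValueError(f"unknown successor at $.transitions.{s}.{sym}.to")
            emit[sidx[s], x] = float(edge["p"])
            nxt[sidx[s], x] = sidx[edge["to"]]
    m = EpsilonMachine(alphabet, states, emit, nxt)
    rep = validate_machine(m)
    if not rep.ok:
        raise ValueError("invalid machine: " + "; ".join(rep.violations))
    return m


def machine_to_dot(m: EpsilonMachine) -> str:
    """GraphViz digraph with edges decorated 'x:p'."""
    lines = ["digraph machine {", "  rankdir=LR;"]
    for s in m.states:
        lines.append(f'  "{s}" [shape=circle];')
    for i, s in enumerate(m.states):
        for x, sym in enumerate(m.alphabet.symbols):
            if m.emit[i, x] > 0:
                to = m.states[int(m.next[i, x])]
                lines.append(f'  "{s}" -> "{to}" [label="{sym}:{m.emit[i, x]:.4g}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
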