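"""Reading and writing substitution-model files.

Two dialects are supported:

* ``paml_dat`` — the PAML layout: 19 whitespace-delimited lines holding the
  lower triangle of the exchangeability matrix (row 2 of the matrix first),
  followed by a line of 20 equilibrium frequencies.  Blank lines are
  ignored; ``#`` starts a comment.
* ``nexus_model`` — a NEXUS ``models`` block with a single named model,
  usable as an IQ-TREE model file.

Frequencies are renormalized to sum to one on read.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Literal

import numpy as np

from .models import SubstitutionModel, matrix_from_lower_triangle

ModelFormat = Literal["paml_dat", "nexus_model"]


class ModelParseError(ValueError):
    """A model file could not be parsed; the message names the line."""


def _numeric_tokens(lines: list[str], path: str) -> list[tuple[float, int]]:
    """(value, 1-based line number) for every token, rejecting non-numbers."""
    out: list[tuple[float, int]] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.split("#", 1)[0]
        for tok in line.split():
            try:
                out.append((float(tok), lineno))
            except ValueError:
                raise ModelParseError(
                    f"{path}:{lineno}: non-numeric token {tok!r}"
                ) from None
    return out


def _model_from_tokens(
    tokens: list[tuple[float, int]], path: str, name: str, source: str
) -> SubstitutionModel:
    if len(tokens) < 210:
        if len(tokens) == 190:
            raise ModelParseError(f"{path}: missing frequency line (found 190 values)")
        raise ModelParseError(
            f"{path}: expected 190 exchangeabilities + 20 frequencies, "
            f"found {len(tokens)} values (last at line {tokens[-1][1] if tokens else 0})"
        )
    if len(tokens) > 210:
        raise ModelParseError(
            f"{path}: expected 210 values, found {len(tokens)} "
            f"(extra at line {tokens[210][1]})"
        )
    values = np.array([v for v, _ in tokens])
    R = matrix_from_lower_triangle(values[:190])
    return SubstitutionModel(name, R, values[190:], source=source)


def read_model_file(
    path: str | Path, format: ModelFormat | None = None, name: str | None = None
) -> SubstitutionModel:
    """Parse a model file; the dialect is inferred from the suffix if omitted."""
    path = Path(path)
    if format is None:
        format = "nexus_model" if path.suffix.lower() in {".nexus", ".nex"} else "paml_dat"
    text = path.read_text()
    if format == "paml_dat":
        tokens = _numeric_tokens(text.splitlines(), str(path))
        return _model_from_tokens(tokens, str(path), name or path.stem, str(path))
    if format == "nexus_model":
        return _read_nexus_model(text, str(path), name)
    raise ValueError(f"unknown model format {format!r}")


_NEXUS_MODEL_RE = re.compile(
    r"model\s+([\w.+-]+)\s*=([^;]*);", re.IGNORECASE | re.DOTALL
)


def _read_nexus_model(text: str, path: str, name: str | None) -> SubstitutionModel:
    if not text.lstrip().lower().startswith("#nexus"):
        raise ModelParseError(f"{path}:1: missing #nexus header")
    matches = _NEXUS_MODEL_RE.findall(text)
    if not matches:
        raise ModelParseError(f"{path}: no 'model <name> = ...;' statement found")
    wanted = None
    for model_name, body in matches:
        if name is None or model_name == name:
            wanted = (model_name, body)
            break
    if wanted is None:
        raise ModelParseError(f"{path}: model {name!r} not found")
    model_name, body = wanted
    # recover line numbers by locating the body within the full text
    offset = text.index(body)
    prefix_lines = text[:offset].count("\n")
    tokens = _numeric_tokens(body.splitlines(), path)
    tokens = [(v, ln + prefix_lines) for v, ln in tokens]
    return _model_from_tokens(tokens, path, model_name, path)


def write_model_file(
    model: SubstitutionModel,
    path: str | Path,
    format: ModelFormat | None = None,
    precision: int = 17,
) -> Path:
    """Write a model at full precision; output round-trips bit-identically."""
    path = Path(path)
    if format is None:
        format = "nexus_model" if path.suffix.lower() in {".nexus", ".nex"} else "paml_dat"
    fmt = f"%.{precision}g"
    R, pi = model.exchangeabilities, model.frequencies
    tri_lines = [
        " ".join(fmt % R[row, col] for col in range(row)) for row in range(1, 20)
    ]
    freq_line = " ".join(fmt % v for v in pi)
    if format == "paml_dat":
        text = "\n".join(tri_lines) + "\n\n" + freq_line + "\n"
    elif format == "nexus_model":
        body = "\n".join("    " + l for l in tri_lines + [freq_line])
        text = (
            "#nexus\n"
            "begin models;\n"
            f"  model {model.name} =\n{body};\n"
            "end;\n"
        )
    else:
        raise ValueError(f"unknown model format {format!r}")
    path.write_text(text)
    return path
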