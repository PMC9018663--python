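"""Read and write spectral libraries in NIST MSP text format.

One MSP entry is written per (compound, cone voltage), named
``"<abbr>@<V>V"``; the ``Comment:`` line carries machine-readable
``Compound=<abbr>; ConeVoltage=<V>V`` fields so generic MSP readers remain
able to load the file.  Intensities are integers on a 0-1000 scale (tenths
of relative percent), which makes serialization lossless with respect to the
library's thresholded relative intensities.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

__all__ = ["MspEntry", "write_msp", "read_msp"]


@dataclass(frozen=True)
class MspEntry:
    name: str
    comment_fields: dict[str, str] = field(default_factory=dict)
    peaks: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("entry name must be non-empty")
        if "ConeVoltage" not in self.comment_fields:
            raise ValueError(f"entry {self.name!r} missing ConeVoltage comment field")
        if "Compound" not in self.comment_fields:
            raise ValueError(f"entry {self.name!r} missing Compound comment field")
        peaks = tuple((int(m), int(i)) for m, i in self.peaks)
        object.__setattr__(self, "peaks", peaks)
        object.__setattr__(self, "comment_fields", dict(self.comment_fields))

    @property
    def num_peaks(self) -> int:
        return len(self.peaks)

    @property
    def cone_voltage(self) -> int:
        return int(str(self.comment_fields["ConeVoltage"]).rstrip("Vv "))

    @property
    def compound(self) -> str:
        return self.comment_fields["Compound"]


def write_msp(entries: Sequence[MspEntry], destination=None) -> str:
    """Serialize ``entries`` to NIST-style MSP text.

    Deterministic: the same entries always produce byte-identical output.
    ``destination`` may be a path or an open text file; the document is also
    returned as a string.
    """
    names = [e.name for e in entries]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ValueError(f"duplicate entry names: {', '.join(dupes)}")
    blocks = []
    for e in entries:
        comment = "; ".join(f"{k}={v}" for k, v in e.comment_fields.items())
        lines = [f"Name: {e.name}", f"Comment: {comment}", f"Num Peaks: {e.num_peaks}"]
        lines += [f"{m} {i}" for m, i in e.peaks]
        blocks.append("\n".join(lines))
    text = "\n\n".join(blocks)
    if blocks:
        text += "\n"
    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            with open(destination, "w", encoding="utf-8", newline="") as fh:
                fh.write(text)
    return text


def _parse_comment(comment: str) -> dict[str, str]:
    """Parse ``key=value`` comment fields separated by ';' (or, failing
    that, whitespace)."""
    fields: dict[str, str] = {}
    parts = comment.split(";") if ";" in comment else re.split(r"\s+(?=\w+=)", comment)
    for part in parts:
        part = part.strip()
        if not part or "=" not in part:
            continue
        k, v = part.split("=", 1)
        fields[k.strip()] = v.strip()
    return fields


def read_msp(source) -> list[MspEntry]:
    """Parse an MSP document (path, file object, or string).

    Tolerant of Windows/Unix line endings and of ';' or whitespace separated
    ``key=value`` comment fields.  Raises on a ``Num Peaks`` count that does
    not match the peak list.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        if not s.strip() or "\n" in s or s.strip().startswith("Name:"):
            text = s
        else:
            with open(s, "r", encoding="utf-8", newline="") as fh:
                text = fh.read()
    text = text.replace("\r\n", "\n").replace("\r", "\n")

    entries: list[MspEntry] = []
    name = None
    comment_fields: dict[str, str] = {}
    declared: int | None = None
    peaks: list[tuple[int, int]] = []

    def flush() -> None:
        nonlocal name, comment_fields, declared, peaks
        if name is None:
            return
        if declared is None:
            raise ValueError(f"entry {name!r} has no 'Num Peaks' line")
        if declared != len(peaks):
            raise ValueError(
                f"entry {name!r} declares Num Peaks: {declared} but has {len(peaks)} peaks"
            )
        entries.append(MspEntry(name=name, comment_fields=comment_fields, peaks=tuple(peaks)))
        name, comment_fields, declared, peaks = None, {}, None, []

    for raw in text.split("\n"):
        line = raw.strip()
        if not line:
            continue
        low = line.lower()
        if low.startswith("name:"):
            flush()
            name = line.split(":", 1)[1].strip()
        elif low.startswith("comment:"):
            comment_fields = _parse_comment(line.split(":", 1)[1].strip())
        elif low.startswith("num peaks:"):
            declared = int(line.split(":", 1)[1].strip())
        elif name is not None and line[0].isdigit():
            bits = re.split(r"[\s;,\t]+", line)
            if len(bits) < 2:
                raise ValueError(f"entry {name!r}: malformed peak line {line!r}")
            peaks.append((int(round(float(bits[0]))), int(round(float(bits[1])))))
        # other header lines (e.g. MW:, Formula:) are ignored
    flush()
    return entries
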