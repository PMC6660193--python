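"""JSON serialization with 17-significant-digit floats and dataclass support."""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Any

import numpy as np


def _convert(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _convert(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _convert(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_convert(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_convert(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        if math.isnan(x):
            return None
        # round-trip exact: 17 significant digits
        return float(f"{x:.17g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def dumps(obj: Any, indent: int = 2) -> str:
    return json.dumps(_convert(obj), indent=indent, sort_keys=False)
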