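"""Shared helpers: seed derivation, display truncation, logging setup."""

from __future__ import annotations

import logging
import math
import zlib

_SEED_MOD = 2**31


def derive_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from one master seed.

    Each pipeline stage (split, clustering, under-sampling, SMOTE, bootstraps)
    draws from its own stream so stages can be replayed in isolation while one
    seed governs the whole run. CRC32 of ``stage`` keeps the result stable
    across processes and below 2**31.
    """
    return (int(seed) + zlib.crc32(stage.encode("utf-8"))) % _SEED_MOD


def floor_quota(x: float) -> int:
    # Guard against an exact ratio landing one ulp below an integer
    # (e.g. 0.3 * 50 == 14.999999999999998 in binary floating point).
    return int(math.floor(x + 1e-9))


def truncate(x: float, decimals: int = 3) -> float:
    """Truncate (not round) towards zero to ``decimals`` places.

    Used only for display: report tables show cluster weights truncated, so
    56/695 = 0.08057... is shown as 0.080 while full precision drives quotas.
    """
    factor = 10.0**decimals
    return math.trunc(x * factor) / factor


def configure_logging(verbosity: int = 0) -> None:
    level = logging.WARNING
    if verbosity == 1:
        level = logging.INFO
    elif verbosity >= 2:
        level = logging.DEBUG
    logging.basicConfig(
        level=level, format="%(levelname)s %(name)s: %(message)s", force=True
    )
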