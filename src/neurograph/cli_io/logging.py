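"""Structured, stage-tagged logging for pipeline runs."""

from __future__ import annotations

import logging
from pathlib import Path

_LOGGER_NAME = "neurograph"
_FORMAT = "%(asctime)s [%(levelname)s] %(message)s"


def get_logger() -> logging.Logger:
    return logging.getLogger(_LOGGER_NAME)


def setup_run_logger(log_file: str | Path | None = None, verbose: bool = False) -> logging.Logger:
    """Console (+ optional file) logger; idempotent per run."""
    logger = get_logger()
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
    for handler in list(logger.handlers):
        logger.removeHandler(handler)
    console = logging.StreamHandler()
    console.setFormatter(logging.Formatter(_FORMAT))
    logger.addHandler(console)
    if log_file is not None:
        fh = logging.FileHandler(log_file, mode="w")
        fh.setFormatter(logging.Formatter(_FORMAT))
        fh.setLevel(logging.DEBUG)
        logger.addHandler(fh)
    return logger


def log_event(level: str, stage: str, message: str) -> None:
    """Timestamped, stage-tagged log line, e.g. ``... [INFO] train: epoch 3``."""
    logger = get_logger()
    logger.log(getattr(logging, level.upper()), "%s: %s", stage, message)
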