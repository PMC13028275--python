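"""Prompt-based vision–language classification harness.

Builds prompts for three paradigms — zero-shot (instruction only), few-shot
(3–5 labeled exemplar images for in-context guidance) and chain-of-thought
(an explicit directive to reason through intermediate morphological cues
before answering) — sends them to a pluggable backend, normalizes the
free-text answer onto the three cell-type labels, and scores the result with
the same metric suite as the learned models.

Only the deterministic mock backend ships with the package: hosted
vision–language APIs are proprietary and out of the offline test surface.
The mock is a pure function of (prompt hash, image file hash), so runs are
reproducible.  Unparseable or failed responses are recorded, count as
incorrect for accuracy, and never enter a precision denominator.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from fusecyte.balance import LeakageError
from fusecyte.constants import CLASSES, CLASS_TO_INDEX
from fusecyte.evalreport import MetricsReport, metrics_from_predictions

logger = logging.getLogger(__name__)

__all__ = [
    "PromptSpec", "LabelParseResult", "MockBackend", "build_prompt",
    "query_backend", "normalize_label", "evaluate_llm", "UNPARSEABLE",
    "STRATEGIES",
]

UNPARSEABLE = "UNPARSEABLE"
STRATEGIES = ("zero_shot", "few_shot", "chain_of_thought")

# Versioned prompt templates; wording is package configuration.
TEMPLATE_VERSION = "1.0"
INSTRUCTION = (
    "You are shown a label-free phase-contrast microscopy image of cultured "
    "cells. Classify the image as exactly one of the following cell types: "
    "astrocyte, cortical, or shsy5y. Answer with the single label."
)
REASONING_DIRECTIVE = (
    "Before answering, reason step by step about the visible morphology: "
    "soma shape, halo, number and branching of processes, and clustering. "
    "Then state your final answer as one label."
)


@dataclass(frozen=True)
class PromptSpec:
    """A fully rendered prompt for one strategy."""

    strategy: str
    instruction_text: str
    exemplars: tuple[tuple[str, str], ...] = ()  # (image reference, label)
    reasoning_directive: str | None = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "zero_shot" and (self.exemplars or self.reasoning_directive):
            raise ValueError("zero_shot prompts carry no exemplars or reasoning directive")
        if self.strategy == "few_shot" and not 3 <= len(self.exemplars) <= 5:
            raise ValueError("few_shot prompts require 3-5 exemplars")
        if self.strategy == "chain_of_thought" and not self.reasoning_directive:
            raise ValueError("chain_of_thought prompts require a reasoning directive")
        missing = [c for c in CLASSES if c not in self.instruction_text]
        if missing:
            raise ValueError(f"instruction must name all three labels; missing {missing}")

    def render(self) -> str:
        parts = [self.instruction_text]
        for i, (ref, label) in enumerate(self.exemplars, start=1):
            parts.append(f"Example {i}: image <{ref}> is a {label}.")
        if self.reasoning_directive:
            parts.append(self.reasoning_directive)
        return "\n".join(parts)

    @property
    def digest(self) -> str:
        return hashlib.sha256(self.render().encode()).hexdigest()[:16]


@dataclass(frozen=True)
class LabelParseResult:
    raw_text: str
    parsed_label: str  # class name or UNPARSEABLE
    matched_pattern: str = ""


def build_prompt(strategy: str,
                 exemplars: Sequence[tuple[str, str]] | None = None) -> PromptSpec:
    """Render a PromptSpec for one prompting paradigm.

    ``exemplars`` (image reference, label pairs) are required for, and only
    for, the few-shot strategy.
    """
    exemplars = tuple((str(ref), str(label)) for ref, label in (exemplars or ()))
    if strategy == "zero_shot":
        if exemplars:
            raise ValueError("zero_shot takes no exemplars")
        return PromptSpec("zero_shot", INSTRUCTION)
    if strategy == "few_shot":
        return PromptSpec("few_shot", INSTRUCTION, exemplars=exemplars)
    if strategy == "chain_of_thought":
        if exemplars:
            raise ValueError("chain_of_thought takes no exemplars")
        return PromptSpec("chain_of_thought", INSTRUCTION,
                          reasoning_directive=REASONING_DIRECTIVE)
    raise ValueError(f"unknown strategy {strategy!r}")


# synonym table; longest patterns first so offsets reflect full matches
_SYNONYMS: list[tuple[str, str]] = [
    ("cortical neuron", "cortical"),
    ("neuronal cortical", "cortical"),
    ("neuroblastoma", "shsy5y"),
    ("sh-sy5y", "shsy5y"),
    ("sh sy5y", "shsy5y"),
    ("shsy5y", "shsy5y"),
    ("astrocytic", "astrocyte"),
    ("astrocyte", "astrocyte"),
    ("cortical", "cortical"),
]


def normalize_label(raw_text: str) -> LabelParseResult:
    """Map free-form model output onto one of the three labels.

    Matching is case-insensitive over a synonym table.  When several classes
    are mentioned, the last occurrence wins — the final-answer convention for
    chain-of-thought transcripts.  Text with no match parses as UNPARSEABLE.
    """
    text = raw_text.lower()
    best: tuple[int, str, str] | None = None  # (offset, label, pattern)
    for pattern, label in _SYNONYMS:
        start = 0
        while True:
            pos = text.find(pattern, start)
            if pos < 0:
                break
            if best is None or pos > best[0]:
                best = (pos, label, pattern)
            start = pos + 1
    if best is None:
        return LabelParseResult(raw_text, UNPARSEABLE)
    return LabelParseResult(raw_text, best[1], best[2])


class BackendError(RuntimeError):
    pass


class MockBackend:
    """Deterministic offline stand-in for a hosted vision–language model.

    Modes:

    * ``"oracle"`` — answers with the true label from ``label_table``;
    * ``"table"`` — echoes a fixed label per image path from ``label_table``;
    * ``"random"`` — a label drawn uniformly from a hash of
      (prompt digest, image file digest, seed); a pure function of its inputs;
    * ``"error"`` — raises, to exercise the harness's failure handling.
    """

    def __init__(self, mode: str = "random",
                 label_table: dict[str, str] | None = None, seed: int = 0):
        if mode not in ("oracle", "table", "random", "error"):
            raise ValueError(f"unknown mock mode {mode!r}")
        self.mode = mode
        self.label_table = {str(k): v for k, v in (label_table or {}).items()}
        self.seed = seed

    def query(self, prompt: PromptSpec, image_ref: str | Path) -> str:
        if self.mode == "error":
            raise BackendError("injected backend failure")
        key = str(image_ref)
        if self.mode in ("oracle", "table"):
            if key not in self.label_table:
                raise BackendError(f"no table entry for {key}")
            return f"This appears to be a {self.label_table[key]}."
        img_digest = hashlib.sha256(Path(image_ref).read_bytes()).hexdigest()
        h = hashlib.sha256(f"{prompt.digest}|{img_digest}|{self.seed}".encode()).digest()
        label = CLASSES[int.from_bytes(h[:4], "big") % len(CLASSES)]
        return f"The morphology suggests {label} cells."


def query_backend(backend, prompt: PromptSpec, image_ref: str | Path,
                  transcript: list | None = None) -> str:
    """Query a backend; failures are recorded as UNPARSEABLE, never dropped."""
    import time
    try:
        text = backend.query(prompt, image_ref)
    except Exception as exc:
        logger.warning("backend failure for %s: %s", image_ref, exc)
        text = UNPARSEABLE
    if transcript is not None:
        transcript.append({
            "timestamp": time.time(), "prompt_hash": prompt.digest,
            "image": str(image_ref), "raw_text": text,
            "parsed_label": normalize_label(text).parsed_label,
        })
    return text


def evaluate_llm(records: Sequence, backend,
                 strategies: Sequence[str] = STRATEGIES,
                 exemplars: Sequence[tuple[str, str]] | None = None,
                 out_csv: str | Path | None = None,
                 transcripts_path: str | Path | None = None,
                 ) -> dict[str, MetricsReport]:
    """Score a backend on manifest records under each prompting strategy.

    Few-shot exemplar images must be disjoint from the evaluation records
    (enforced; overlap raises :class:`~fusecyte.balance.LeakageError`).
    Returns one MetricsReport per strategy and optionally writes a results
    CSV plus a JSONL transcript of every query.
    """
    exemplars = tuple(exemplars or ())
    exemplar_paths = {str(ref) for ref, _ in exemplars}
    overlap = [r.path for r in records if str(r.path) in exemplar_paths]
    if overlap:
        raise LeakageError(f"exemplar images appear in the evaluation set: {overlap}")

    transcript: list[dict] = []
    reports: dict[str, MetricsReport] = {}
    for strategy in strategies:
        prompt = build_prompt(strategy, exemplars if strategy == "few_shot" else None)
        preds = []
        for rec in records:
            text = query_backend(backend, prompt, rec.path, transcript)
            parsed = normalize_label(text).parsed_label
            preds.append(CLASS_TO_INDEX.get(parsed, -1))
        y_true = np.array([CLASS_TO_INDEX[r.label] for r in records])
        reports[strategy] = metrics_from_predictions(y_true, np.array(preds))

    if out_csv is not None:
        with open(out_csv, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["model", "strategy", "accuracy", "f1", "precision", "recall"])
            name = type(backend).__name__
            for strategy, rep in reports.items():
                writer.writerow([name, strategy, f"{rep.accuracy:.2f}",
                                 f"{rep.macro_f1:.2f}", f"{rep.macro_precision:.2f}",
                                 f"{rep.macro_recall:.2f}"])
    if transcripts_path is not None:
        with open(transcripts_path, "w", encoding="utf-8") as fh:
            for row in transcript:
                fh.write(json.dumps(row) + "\n")
    return reports
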