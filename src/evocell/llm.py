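"""LLM-assisted hypothesis generation and result explanation.

A provider contract abstracts the model backend: a deterministic scripted
mock (used everywhere in tests), an OpenAI-compatible HTTP backend and an
Ollama-compatible HTTP backend (both integration-only). Prompts come in two
modes: the *engineered* hypothesis prompt supplies dataset context and
demands, for every proposed cell-state transition, at least three
publication titles in a machine-parseable fenced layout so they can be
verified downstream; the *naive* prompt only asks for transitions.
Precision/recall evaluation across repeated runs quantifies the difference
between the two prompting strategies.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

from .errors import (
    ParameterError,
    PromptError,
    ProviderParseError,
    ProviderTransportError,
)

logger = logging.getLogger(__name__)

DEFAULT_TEMPERATURE = 0.7
MIN_TITLES_PER_TRANSITION = 3
EXPLAIN_TOP_K = 25

FENCE = "```"


@runtime_checkable
class LlmProvider(Protocol):
    """Minimal completion contract all backends implement."""

    provider_name: str

    def complete(
        self, prompt: str, temperature: float = DEFAULT_TEMPERATURE, seed: int | None = None
    ) -> str: ...


class MockProvider:
    """Scripted, offline provider: a pure function of (prompt, seed).

    The script is a list of rules ``{"contains": <substring>, "response":
    <text or list of texts>}`` checked in order; the first rule whose
    ``contains`` string occurs in the prompt wins. When ``response`` is a
    list, ``seed`` (mod the list length) selects the variant, emulating
    run-to-run sampling variability deterministically.
    """

    provider_name = "mock"

    def __init__(self, script: list[dict]):
        self.script = list(script)

    @classmethod
    def from_json(cls, path: str | Path) -> "MockProvider":
        return cls(json.loads(Path(path).read_text()))

    def complete(
        self, prompt: str, temperature: float = DEFAULT_TEMPERATURE, seed: int | None = None
    ) -> str:
        if not 0.0 <= temperature <= 2.0:
            raise ParameterError(f"temperature must be in [0, 2], got {temperature}")
        for rule in self.script:
            if rule.get("contains", "") in prompt:
                response = rule["response"]
                if isinstance(response, list):
                    if not response:
                        raise ProviderTransportError("scripted rule has no responses")
                    return response[(seed or 0) % len(response)]
                return response
        raise ProviderTransportError("no scripted response matches the prompt")


class OpenAICompatProvider:
    """Chat-completions backend for OpenAI-compatible HTTP endpoints.

    Integration-only: never exercised by the offline test suite. The API key
    is read from the environment variable named in the config, never stored.
    """

    provider_name = "openai"

    def __init__(self, endpoint: str, model: str, api_key_env: str = "OPENAI_API_KEY",
                 timeout: float = 60.0):
        self.endpoint = endpoint.rstrip("/")
        self.model = model
        self.api_key_env = api_key_env
        self.timeout = timeout

    def complete(self, prompt, temperature=DEFAULT_TEMPERATURE, seed=None):
        import os

        import requests

        headers = {}
        key = os.environ.get(self.api_key_env)
        if key:
            headers["Authorization"] = f"Bearer {key}"
        body = {
            "model": self.model,
            "messages": [{"role": "user", "content": prompt}],
            "temperature": temperature,
        }
        if seed is not None:
            body["seed"] = seed
        try:
            resp = requests.post(
                f"{self.endpoint}/chat/completions", json=body,
                headers=headers, timeout=self.timeout,
            )
            resp.raise_for_status()
            return resp.json()["choices"][0]["message"]["content"]
        except Exception as exc:  # noqa: BLE001 - map any transport issue
            raise ProviderTransportError(str(exc)) from exc


class OllamaProvider:
    """Local Ollama-compatible backend. Integration-only."""

    provider_name = "ollama"

    def __init__(self, endpoint: str = "http://localhost:11434", model: str = "llama3",
                 timeout: float = 120.0):
        self.endpoint = endpoint.rstrip("/")
        self.model = model
        self.timeout = timeout

    def complete(self, prompt, temperature=DEFAULT_TEMPERATURE, seed=None):
        import requests

        body = {
            "model": self.model,
            "prompt": prompt,
            "stream": False,
            "options": {"temperature": temperature, **({"seed": seed} if seed is not None else {})},
        }
        try:
            resp = requests.post(f"{self.endpoint}/api/generate", json=body, timeout=self.timeout)
            resp.raise_for_status()
            return resp.json()["response"]
        except Exception as exc:  # noqa: BLE001
            raise ProviderTransportError(str(exc)) from exc


def load_provider_config(path: str | Path) -> dict:
    import yaml

    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if "provider" not in cfg:
        raise ParameterError("provider config is missing the 'provider' key")
    return cfg


def make_provider(cfg: dict) -> LlmProvider:
    name = cfg["provider"]
    if name == "mock":
        return MockProvider.from_json(cfg["script"])
    if name == "openai":
        return OpenAICompatProvider(
            endpoint=cfg.get("endpoint", "https://api.openai.com/v1"),
            model=cfg.get("model", "gpt-4o-mini"),
            api_key_env=cfg.get("api_key_env", "OPENAI_API_KEY"),
        )
    if name == "ollama":
        return OllamaProvider(
            endpoint=cfg.get("endpoint", "http://localhost:11434"),
            model=cfg.get("model", "llama3"),
        )
    raise ParameterError(f"unknown provider {name!r}")


# --------------------------------------------------------------------------
# Prompt templates
# --------------------------------------------------------------------------

CITATION_INSTRUCTION = (
    "For every transition, list at least three PubMed publication titles "
    "that support it."
)

_OUTPUT_CONTRACT = (
    f"Answer inside a single {FENCE} fenced block using only these line "
    "forms:\n"
    "TRANSITION: <from_state> -> <to_state>\n"
    "RATIONALE: <one sentence>\n"
    "TITLE: <publication title>\n"
)

_TEMPLATES: dict[tuple[str, str], tuple[str, tuple[str, ...]]] = {
    # (mode, template_id) -> (template, required context fields)
    ("engineered", "hypothesis"): (
        "Template: engineered-hypothesis-v1\n"
        "You are analyzing a single-cell trajectory from this experiment: "
        "{experiment}\n"
        "The dataset contains these cell states: {states}.\n"
        "Identify the biologically plausible cell state transitions among "
        "them, restricted to the states listed above. "
        + CITATION_INSTRUCTION + "\n" + _OUTPUT_CONTRACT,
        ("states", "experiment"),
    ),
    ("naive", "hypothesis"): (
        "Template: naive-hypothesis-v1\n"
        "Which cell state transitions are possible among these cell states: "
        "{states}?\n" + _OUTPUT_CONTRACT,
        ("states",),
    ),
    ("engineered", "claim_citations"): (
        "Template: claim-citations-v1\n"
        "Claim: {claim}\n"
        "List up to five PubMed publication titles that directly support "
        "this claim.\n"
        f"Answer inside a single {FENCE} fenced block with one line per "
        "title, each of the form:\nTITLE: <publication title>\n",
        ("claim",),
    ),
    ("engineered", "explain"): (
        "Template: explain-v1\n"
        "Experiment: {experiment}\n"
        "Analysis step: {subject}\n"
        "Top results:\n{payload}\n"
        "Explain what these results suggest in the context of the "
        "experiment, in plain scientific prose.\n",
        ("experiment", "subject", "payload"),
    ),
}


@dataclass
class PromptBundle:
    mode: str  # engineered | naive
    template_id: str
    rendered_text: str
    context_fields: dict


@dataclass
class TransitionHypothesis:
    from_state: str
    to_state: str
    rationale: str = ""
    candidate_titles: list[str] = field(default_factory=list)
    verified_citations: list[tuple[str, str]] = field(default_factory=list)  # (title, pmid)
    prompt_compliant: bool = True

    @property
    def transition(self) -> tuple[str, str]:
        return (self.from_state, self.to_state)


@dataclass
class Explanation:
    text: str
    prompt: str


@dataclass
class PromptEvalReport:
    precision_per_run: list[float]
    recall_per_run: list[float | None]
    precision_mean: float
    precision_sd: float
    recall_mean: float | None
    recall_sd: float | None
    flags: list[str] = field(default_factory=list)
    temperature: float | None = None


def build_prompt(mode: str, template_id: str, context: dict) -> PromptBundle:
    """Render a prompt template deterministically from its context fields."""
    if mode not in ("engineered", "naive"):
        raise ParameterError(f"unknown prompt mode {mode!r}")
    key = (mode, template_id)
    if key not in _TEMPLATES:
        raise PromptError(f"no template {template_id!r} for mode {mode!r}")
    template, required = _TEMPLATES[key]
    rendered_context = {}
    for name in required:
        if name not in context:
            raise PromptError(f"missing required context field {name!r}")
        value = context[name]
        if isinstance(value, (set, frozenset)):
            value = ", ".join(sorted(value))
        elif isinstance(value, (list, tuple)):
            value = ", ".join(str(v) for v in value)
        rendered_context[name] = str(value)
    return PromptBundle(
        mode=mode,
        template_id=template_id,
        rendered_text=template.format(**rendered_context),
        context_fields=rendered_context,
    )


def _extract_fenced(text: str) -> str:
    parts = text.split(FENCE)
    if len(parts) < 3:
        raise ProviderParseError("no fenced block in provider output", raw_text=text)
    # first fenced block; drop an optional language tag on the opening line
    block = parts[1]
    if block.startswith(("text\n", "txt\n")):
        block = block.split("\n", 1)[1]
    return block


def parse_hypothesis_response(text: str) -> list[TransitionHypothesis]:
    """Parse the fenced TRANSITION/RATIONALE/TITLE layout.

    Tolerant of prose outside the fence, strict inside it.
    """
    block = _extract_fenced(text)
    hypotheses: list[TransitionHypothesis] = []
    current: TransitionHypothesis | None = None
    for lineno, line in enumerate(block.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.upper().startswith("TRANSITION:"):
            body = stripped.split(":", 1)[1]
            if "->" not in body:
                raise ProviderParseError(
                    f"malformed TRANSITION line {lineno}: {stripped!r}", raw_text=text
                )
            frm, _, to = body.partition("->")
            frm, to = frm.strip(), to.strip()
            if not frm or not to:
                raise ProviderParseError(
                    f"empty state in TRANSITION line {lineno}: {stripped!r}", raw_text=text
                )
            current = TransitionHypothesis(from_state=frm, to_state=to)
            hypotheses.append(current)
        elif stripped.upper().startswith("RATIONALE:"):
            if current is None:
                raise ProviderParseError(
                    f"RATIONALE before any TRANSITION at line {lineno}", raw_text=text
                )
            current.rationale = stripped.split(":", 1)[1].strip()
        elif stripped.upper().startswith("TITLE:"):
            if current is None:
                raise ProviderParseError(
                    f"TITLE before any TRANSITION at line {lineno}", raw_text=text
                )
            title = stripped.split(":", 1)[1].strip()
            if title:
                current.candidate_titles.append(title)
        else:
            raise ProviderParseError(
                f"unrecognized line {lineno} inside fence: {stripped!r}", raw_text=text
            )
    return hypotheses


def parse_title_response(text: str) -> list[str]:
    """Parse a fenced block of TITLE lines (claim-citation prompts)."""
    block = _extract_fenced(text)
    titles = []
    for lineno, line in enumerate(block.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.upper().startswith("TITLE:"):
            raise ProviderParseError(
                f"unrecognized line {lineno} inside fence: {stripped!r}", raw_text=text
            )
        title = stripped.split(":", 1)[1].strip()
        if title:
            titles.append(title)
    return titles


def generate_hypotheses(
    provider: LlmProvider,
    states: set[str] | list[str],
    context: dict | None = None,
    mode: str = "engineered",
    temperature: float = DEFAULT_TEMPERATURE,
    seed: int | None = None,
) -> list[TransitionHypothesis]:
    """Propose cell-state transitions restricted to the dataset's inventory.

    Out-of-inventory or self transitions are dropped (with a logged reason),
    duplicates are merged, and in engineered mode a hypothesis returning
    fewer than three candidate titles is flagged non-compliant rather than
    silently accepted.
    """
    inventory = set(states)
    if len(inventory) < 2:
        raise ParameterError("need at least two cell states to hypothesize transitions")
    ctx = dict(context or {})
    ctx.setdefault("states", sorted(inventory))
    ctx.setdefault("experiment", "unspecified experiment")
    bundle = build_prompt(mode, "hypothesis", ctx)
    raw = provider.complete(bundle.rendered_text, temperature=temperature, seed=seed)
    parsed = parse_hypothesis_response(raw)

    seen: dict[tuple[str, str], TransitionHypothesis] = {}
    for hyp in parsed:
        if hyp.from_state not in inventory or hyp.to_state not in inventory:
            logger.info(
                "dropping transition %s -> %s: state outside inventory",
                hyp.from_state, hyp.to_state,
            )
            continue
        if hyp.from_state == hyp.to_state:
            logger.info("dropping self-transition %s -> %s", hyp.from_state, hyp.to_state)
            continue
        if hyp.transition in seen:
            seen[hyp.transition].candidate_titles.extend(hyp.candidate_titles)
        else:
            seen[hyp.transition] = hyp
    result = list(seen.values())
    if mode == "engineered":
        for hyp in result:
            if len(hyp.candidate_titles) < MIN_TITLES_PER_TRANSITION:
                hyp.prompt_compliant = False
                logger.warning(
                    "transition %s -> %s returned %d titles (< %d): prompt-compliance failure",
                    hyp.from_state, hyp.to_state,
                    len(hyp.candidate_titles), MIN_TITLES_PER_TRANSITION,
                )
    return result


def _summarize_payload(subject: str, payload, top_k: int) -> str:
    if subject == "dge":
        rows = sorted(payload, key=lambda r: -abs(r.log2fc))[:top_k]
        return "\n".join(
            f"{r.gene}: log2FC={r.log2fc:.3f}, adj.p={r.p_adjusted:.3g}" for r in rows
        )
    if subject == "drivers":
        rows = sorted(payload, key=lambda r: -abs(r.correlation))[:top_k]
        return "\n".join(
            f"{r.gene}: rho={r.correlation:.3f} ({r.direction}), adj.p={r.p_adjusted:.3g}"
            for r in rows
        )
    if subject == "gsea":
        rows = sorted(payload, key=lambda r: (r.fdr_q, -abs(r.nes)))[:top_k]
        return "\n".join(
            f"{r.set_name}: NES={r.nes:.3f}, FDR q={r.fdr_q:.3g}" for r in rows
        )
    if subject == "path":
        return " -> ".join(payload.milestone_sequence) + (
            f" ({payload.start_state} to {payload.end_state})"
        )
    if subject == "terminal":
        pairs = zip(payload.terminal_milestones, payload.terminal_states)
        return "\n".join(f"{m}: {s}" for m, s in pairs)
    raise ParameterError(f"unknown explanation subject {subject!r}")


def explain(
    provider: LlmProvider,
    subject: str,
    payload,
    context: dict | None = None,
    top_k: int = EXPLAIN_TOP_K,
    temperature: float = DEFAULT_TEMPERATURE,
    seed: int | None = None,
) -> Explanation:
    """Ask the provider to interpret an analysis result.

    The payload is summarized to its ``top_k`` most salient records before
    templating; the rendered prompt is returned alongside the provider text
    for auditability.
    """
    if payload is None or (hasattr(payload, "__len__") and len(payload) == 0):
        raise ParameterError("empty payload cannot be explained")
    ctx = dict(context or {})
    ctx.setdefault("experiment", "unspecified experiment")
    ctx["subject"] = subject
    ctx["payload"] = _summarize_payload(subject, payload, top_k)
    bundle = build_prompt("engineered", "explain", ctx)
    text = provider.complete(bundle.rendered_text, temperature=temperature, seed=seed)
    return Explanation(text=text, prompt=bundle.rendered_text)


def evaluate_prompting(
    predicted_runs: list[set[tuple[str, str]]],
    truth: set[tuple[str, str]],
    temperature: float | None = None,
) -> PromptEvalReport:
    """Precision/recall of predicted transition sets against ground truth.

    Per run: precision = |pred ∩ truth| / |pred| (defined as 1.0 for an
    empty prediction set — no false positives — and flagged); recall =
    |pred ∩ truth| / |truth| (flagged null when truth is empty). Mean and
    sample standard deviation are reported across runs.
    """
    if not predicted_runs:
        raise ParameterError("need at least one run")
    flags: list[str] = []
    precisions: list[float] = []
    recalls: list[float | None] = []
    for i, pred in enumerate(predicted_runs):
        tp = len(set(pred) & truth)
        if pred:
            precisions.append(tp / len(pred))
        else:
            precisions.append(1.0)
            flags.append(f"run {i}: empty prediction set; precision 1.0 by convention")
        if truth:
            recalls.append(tp / len(truth))
        else:
            recalls.append(None)
            flags.append(f"run {i}: empty truth set; recall undefined")

    def _mean_sd(values: list[float]) -> tuple[float, float]:
        n = len(values)
        mean = sum(values) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1)) if n > 1 else 0.0
        return mean, sd

    p_mean, p_sd = _mean_sd(precisions)
    defined_recalls = [r for r in recalls if r is not None]
    if defined_recalls:
        r_mean, r_sd = _mean_sd(defined_recalls)
    else:
        r_mean = r_sd = None
    return PromptEvalReport(
        precision_per_run=precisions,
        recall_per_run=recalls,
        precision_mean=p_mean,
        precision_sd=p_sd,
        recall_mean=r_mean,
        recall_sd=r_sd,
        flags=flags,
        temperature=temperature,
    )
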