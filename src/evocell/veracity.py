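"""Citation verification against PubMed titles.

An LLM-proposed publication title is accepted when it shares a sufficiently
long run of consecutive words with a real PubMed title, after folding word
variants: titles are unicode-folded, lower-cased, stripped of punctuation
(hyphens split tokens, digits are kept) and each token is stemmed. The
match statistic is the longest common *contiguous* stemmed-token
subsequence; the default acceptance threshold is a run of 5.

Two interchangeable PubMed clients implement the search contract: an
offline fixture store (used by all tests) and a live NCBI E-utilities
client with rate limiting and exponential backoff (integration-only).
"""

from __future__ import annotations

import json
import re
import time
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

from ._porter import stem
from .errors import ParameterError, PubMedTransportError
from .llm import LlmProvider, build_prompt, parse_title_response, TransitionHypothesis

DEFAULT_THRESHOLD = 5

_NON_WORD = re.compile(r"[^a-z0-9\s]+")


@dataclass
class NormalizedTitle:
    original: str
    tokens: list[str]


@dataclass
class VerificationResult:
    candidate_title: str
    matched: bool
    best_run_length: int
    matched_pmid: str | None = None
    matched_title: str | None = None
    matched_span: tuple[tuple[int, int], tuple[int, int]] | None = None  # (cand, ref)

    def to_dict(self) -> dict:
        return {
            "candidate_title": self.candidate_title,
            "matched": self.matched,
            "best_run_length": self.best_run_length,
            "matched_pmid": self.matched_pmid,
            "matched_title": self.matched_title,
            "matched_span": self.matched_span,
        }


@runtime_checkable
class PubMedClient(Protocol):
    def search(self, query: str, max_results: int = 20) -> list[tuple[str, str]]:
        """Return (pmid, title) records for a query."""
        ...


def _stem_fixed_point(token: str, max_rounds: int = 5) -> str:
    # stemming to a fixed point makes normalization idempotent: a stemmed
    # token re-normalizes to itself
    for _ in range(max_rounds):
        nxt = stem(token)
        if nxt == token:
            return token
        token = nxt
    return token


def normalize_title(title: str) -> NormalizedTitle:
    """Deterministic normalization: unicode-fold, lowercase, strip
    punctuation (hyphens separate tokens), split, stem each token.

    Idempotent: normalizing the joined tokens reproduces them."""
    if not title or not title.strip():
        raise ParameterError("empty title")
    folded = unicodedata.normalize("NFKD", title)
    folded = "".join(c for c in folded if not unicodedata.combining(c))
    folded = folded.lower().replace("-", " ")
    folded = _NON_WORD.sub(" ", folded)
    tokens = [_stem_fixed_point(t) for t in folded.split()]
    return NormalizedTitle(original=title, tokens=[t for t in tokens if t])


def longest_consecutive_match(
    a: NormalizedTitle, b: NormalizedTitle
) -> tuple[int, tuple[int, int], tuple[int, int]]:
    """Longest common contiguous token run between two normalized titles.

    Returns (run_length, span_a, span_b) with half-open token spans; spans
    are (0, 0) when the token sets are disjoint.
    """
    ta, tb = a.tokens, b.tokens
    best = 0
    end_a = end_b = 0
    prev = [0] * (len(tb) + 1)
    for i in range(1, len(ta) + 1):
        cur = [0] * (len(tb) + 1)
        for j in range(1, len(tb) + 1):
            if ta[i - 1] == tb[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
                    end_a, end_b = i, j
        prev = cur
    return best, (end_a - best, end_a), (end_b - best, end_b)


class FixturePubMedClient:
    """Offline PubMed stand-in over a JSON store of {pmid, title} records.

    Search ranks records by the number of stemmed tokens shared with the
    query and returns those sharing at least one token. Pure and offline.
    """

    def __init__(self, records: list[dict]):
        self.records = [(str(r["pmid"]), r["title"]) for r in records]
        self._tokens = [set(normalize_title(t).tokens) for _, t in self.records]

    @classmethod
    def from_json(cls, path: str | Path) -> "FixturePubMedClient":
        return cls(json.loads(Path(path).read_text()))

    def search(self, query: str, max_results: int = 20) -> list[tuple[str, str]]:
        q = query.strip().strip('"')
        if not q.strip():
            return []
        q_tokens = set(normalize_title(q).tokens)
        scored = [
            (len(q_tokens & toks), i)
            for i, toks in enumerate(self._tokens)
            if q_tokens & toks
        ]
        scored.sort(key=lambda s: (-s[0], s[1]))
        return [self.records[i] for _, i in scored[:max_results]]


class EntrezPubMedClient:
    """Live NCBI E-utilities client (esearch + esummary on pubmed).

    Budgeted at 3 requests/second with exponential backoff; HTTP failures
    surface as PubMedTransportError. Integration-only — the test suite uses
    the fixture client exclusively.
    """

    BASE = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"

    def __init__(self, email: str = "", api_key: str = "", max_retries: int = 3):
        self.email = email
        self.api_key = api_key
        self.max_retries = max_retries
        self._last_request = 0.0

    def _throttle(self) -> None:
        wait = self._last_request + 1.0 / 3.0 - time.monotonic()
        if wait > 0:
            time.sleep(wait)
        self._last_request = time.monotonic()

    def _get(self, url: str, params: dict) -> dict:
        import requests

        if self.email:
            params["email"] = self.email
        if self.api_key:
            params["api_key"] = self.api_key
        delay = 1.0
        for attempt in range(self.max_retries):
            self._throttle()
            try:
                resp = requests.get(url, params=params, timeout=30)
                resp.raise_for_status()
                return resp.json()
            except Exception as exc:  # noqa: BLE001
                if attempt == self.max_retries - 1:
                    raise PubMedTransportError(str(exc)) from exc
                time.sleep(delay)
                delay *= 2
        raise PubMedTransportError("unreachable")

    def search(self, query: str, max_results: int = 20) -> list[tuple[str, str]]:
        data = self._get(
            f"{self.BASE}/esearch.fcgi",
            {"db": "pubmed", "term": query, "retmax": max_results, "retmode": "json"},
        )
        ids = data.get("esearchresult", {}).get("idlist", [])
        if not ids:
            return []
        summ = self._get(
            f"{self.BASE}/esummary.fcgi",
            {"db": "pubmed", "id": ",".join(ids), "retmode": "json"},
        )
        result = summ.get("result", {})
        return [(pmid, result[pmid]["title"]) for pmid in ids if pmid in result]


def verify_title(
    candidate: str, client: PubMedClient, threshold: int = DEFAULT_THRESHOLD
) -> VerificationResult:
    """Check one candidate title against PubMed.

    Queries the client with the quoted candidate, falling back to the
    unquoted form, and reports the best consecutive stemmed-token run over
    all returned titles; matched iff best run >= threshold.
    """
    if not candidate or not candidate.strip():
        raise ParameterError("empty candidate title")
    if threshold < 1:
        raise ParameterError(f"threshold must be >= 1, got {threshold}")
    hits = client.search(f'"{candidate}"')
    if not hits:
        hits = client.search(candidate)
    cand_norm = normalize_title(candidate)
    best = VerificationResult(candidate_title=candidate, matched=False, best_run_length=0)
    for pmid, title in hits:
        run, span_c, span_r = longest_consecutive_match(cand_norm, normalize_title(title))
        if run > best.best_run_length:
            best = VerificationResult(
                candidate_title=candidate,
                matched=False,
                best_run_length=run,
                matched_pmid=pmid,
                matched_title=title,
                matched_span=(span_c, span_r),
            )
    best.matched = best.best_run_length >= threshold
    if not best.matched:
        best.matched_pmid = None
        best.matched_title = None
        best.matched_span = None
    return best


def verify_hypotheses(
    hypotheses: list[TransitionHypothesis],
    client: PubMedClient,
    threshold: int = DEFAULT_THRESHOLD,
) -> list[TransitionHypothesis]:
    """Populate verified_citations on each hypothesis from its candidate
    titles; returns the same hypotheses for chaining."""
    for hyp in hypotheses:
        hyp.verified_citations = []
        for title in hyp.candidate_titles:
            result = verify_title(title, client, threshold)
            if result.matched:
                hyp.verified_citations.append((result.matched_title, result.matched_pmid))
    return hypotheses


def filter_supported(hypotheses: list[TransitionHypothesis]) -> list[TransitionHypothesis]:
    """Keep only hypotheses with at least one verified citation."""
    return [h for h in hypotheses if h.verified_citations]


@dataclass
class ClaimVerdict:
    claim: str
    verdict: str  # "supported" | "not_found"
    citations: list[VerificationResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "claim": self.claim,
            "verdict": self.verdict,
            "citations": [c.to_dict() for c in self.citations],
        }


def verify_claim(
    claim: str,
    provider: LlmProvider,
    client: PubMedClient,
    threshold: int = DEFAULT_THRESHOLD,
    temperature: float = 0.7,
    seed: int | None = None,
) -> ClaimVerdict:
    """Veracity filter for a free-text claim.

    The provider proposes candidate publication titles for the claim; each
    is verified against PubMed, and the claim is 'supported' iff at least
    one candidate matches.
    """
    if not claim or not claim.strip():
        raise ParameterError("empty claim")
    bundle = build_prompt("engineered", "claim_citations", {"claim": claim})
    raw = provider.complete(bundle.rendered_text, temperature=temperature, seed=seed)
    titles = parse_title_response(raw)
    results = [verify_title(t, client, threshold) for t in titles]
    verdict = "supported" if any(r.matched for r in results) else "not_found"
    return ClaimVerdict(claim=claim, verdict=verdict, citations=results)
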