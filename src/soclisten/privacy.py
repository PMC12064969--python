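"""Identifier obfuscation and PII redaction.

Platform identifiers (post IDs, usernames) are replaced by salted keyed-hash
tokens re-encoded in base 36, so that equality structure is preserved (the
same author always maps to the same token) while the original values are
unrecoverable without the salt.  Free text is scrubbed of personally
identifiable spans — emails, phone numbers, URLs and u/-style username
mentions by default — each replaced by a labelled placeholder.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Pattern, Sequence

__all__ = [
    "ObfuscationConfig",
    "Obfuscator",
    "RedactionRule",
    "DEFAULT_REDACTION_RULES",
    "obfuscate",
    "redact",
    "make_redactor",
]

_BASE36 = "0123456789abcdefghijklmnopqrstuvwxyz"


class ConfigurationError(ValueError):
    """Raised for unusable privacy configuration (e.g. an empty salt)."""


@dataclass(frozen=True)
class ObfuscationConfig:
    """Parameters of the one-way identifier tokenizer.

    The salt is a secret: it never appears in any output artifact, and an
    empty salt is refused outright rather than silently producing
    unsalted (dictionary-attackable) tokens.
    """

    salt: str
    token_length: int = 10

    def __post_init__(self) -> None:
        if not self.salt:
            raise ConfigurationError("obfuscation salt must be non-empty")
        if self.token_length < 1:
            raise ConfigurationError("token_length must be positive")


def _to_base36(n: int) -> str:
    if n == 0:
        return "0"
    digits = []
    while n:
        n, r = divmod(n, 36)
        digits.append(_BASE36[r])
    return "".join(reversed(digits))


def obfuscate(value: str, config: ObfuscationConfig) -> str:
    """Deterministic one-way base-36 token for an identifier.

    Uses BLAKE2b keyed with the salt; the 128-bit digest is reduced to
    ``token_length`` base-36 digits (zero-padded on the left).
    """
    if not value:
        raise ValueError("cannot obfuscate an empty identifier")
    digest = hashlib.blake2b(
        value.encode("utf-8"),
        key=config.salt.encode("utf-8"),
        digest_size=16,
    ).digest()
    token = _to_base36(int.from_bytes(digest, "big"))
    # 16 bytes ~ 24.8 base-36 digits; truncate to the requested length
    return token.rjust(config.token_length, "0")[-config.token_length :]


class Obfuscator:
    """Callable wrapper binding a config, convenient for pipelines."""

    def __init__(self, config: ObfuscationConfig):
        self.config = config

    def __call__(self, value: str) -> str:
        return obfuscate(value, self.config)


@dataclass(frozen=True)
class RedactionRule:
    label: str
    pattern: Pattern[str]
    replacement: str

    def __post_init__(self) -> None:
        if self.label not in self.replacement:
            raise ConfigurationError(
                f"replacement {self.replacement!r} must contain label "
                f"{self.label!r}"
            )


def _rule(label: str, pattern: str) -> RedactionRule:
    return RedactionRule(label, re.compile(pattern), f"[REDACTED_{label}]")


#: Floor rule set; rules are applied in order (URLs before username mentions
#: so a u/ path segment inside a link is swallowed by the URL rule).
DEFAULT_REDACTION_RULES: tuple[RedactionRule, ...] = (
    _rule("EMAIL", r"[A-Za-z0-9._%+-]+@[A-Za-z0-9.-]+\.[A-Za-z]{2,}"),
    _rule("URL", r"(?:https?://|www\.)[^\s\]\)>]+"),
    _rule(
        "PHONE",
        r"(?<!\d)(?:\+?1[ \-.]?)?(?:\(\d{3}\)[ \-.]?|\d{3}[\-.])\d{3}[\-.]\d{4}(?!\d)",
    ),
    _rule("USERNAME_MENTION", r"(?<![\w/])/?u/[A-Za-z0-9_\-]+"),
)


def redact(
    text: str, rules: Sequence[RedactionRule] = DEFAULT_REDACTION_RULES
) -> tuple[str, dict[str, int]]:
    """Replace every PII span with its rule's placeholder.

    Returns the scrubbed text and a per-rule replacement count.
    Idempotent: placeholders contain no characters matchable by the
    default rules, so re-redacting is a no-op.
    """
    if not rules:
        raise ConfigurationError("at least one redaction rule is required")
    counts: dict[str, int] = {r.label: 0 for r in rules}
    for rule in rules:
        text, n = rule.pattern.subn(rule.replacement, text)
        counts[rule.label] += n
    return text, counts


def make_redactor(rules: Sequence[RedactionRule] = DEFAULT_REDACTION_RULES):
    """Text-to-text closure over :func:`redact`, for use in normalization."""

    def _redact(text: str) -> str:
        return redact(text, rules)[0]

    return _redact
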