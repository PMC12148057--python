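"""LLM backend dispatch: Google / OpenAI / Ollama HTTP contracts plus a
deterministic replay store for offline runs and tests.

The replay store is a JSON mapping ``task_id -> {"default": text,
"<fingerprint>": text, ...}`` (a bare string is treated as the default).
Fingerprints are a stable hash of the rendered prompt so canned responses
can be pinned to exact prompts, with a per-task default fallback so metric
jitter does not break replay.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

from ._errors import BackendError, ConfigError
from .prompt_engine import AugmentedPrompt

log = logging.getLogger(__name__)

SUPPORTED_SERVERS = ("google", "openai", "ollama", "replay")

DEFAULT_MODELS = {
    "google": "gemini-1.5-flash-latest",
    "openai": "gpt-4o-mini",
    "ollama": "llama3",
    "replay": "replay",
}

_RETRYABLE_STATUS = range(500, 600)


@dataclass
class BackendConfig:
    server: str
    model_id: str | None = None
    api_key_file: str | Path | None = None
    base_url: str | None = None
    temperature: float = 0.0
    timeout: float = 60.0
    max_retries: int = 3
    fixture_store: str | Path | dict | None = None
    _store_cache: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.server not in SUPPORTED_SERVERS:
            raise ConfigError(
                f"unknown LLM server {self.server!r}; supported servers: "
                f"{', '.join(SUPPORTED_SERVERS)}"
            )
        if self.model_id is None:
            self.model_id = DEFAULT_MODELS[self.server]
        if self.server in ("google", "openai") and self.api_key_file is None:
            raise ConfigError(
                f"server {self.server!r} requires an API key file "
                "(api_key_file)"
            )
        if self.server == "replay" and self.fixture_store is None:
            raise ConfigError("replay backend requires a fixture store path")


@dataclass
class LLMResponse:
    text: str
    model_id: str
    finish_reason: str = "stop"
    token_usage: dict | None = None


def read_api_key(path: str | Path) -> str:
    """First line of the key file, whitespace-stripped; never logged."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"API key file not found: {path}")
    first_line = path.read_text(encoding="utf-8").splitlines()
    key = first_line[0].strip() if first_line else ""
    if not key:
        raise ConfigError(f"API key file {path} is empty")
    return key


def make_replay_backend(fixture_store_path: str | Path | dict) -> BackendConfig:
    return BackendConfig(server="replay", fixture_store=fixture_store_path)


def prompt_fingerprint(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()[:16]


def complete(cfg: BackendConfig, prompt: AugmentedPrompt) -> LLMResponse:
    """Submit an augmented prompt and return the raw completion.

    Transient failures (5xx, timeouts) are retried with exponential
    backoff up to ``cfg.max_retries``; 4xx fails fast.  The API key is
    read only at call time and never echoed.
    """
    if cfg.server == "replay":
        return _complete_replay(cfg, prompt)
    if cfg.server in ("google", "openai"):
        key = read_api_key(cfg.api_key_file)
    else:
        key = ""
    request = _build_request(cfg, prompt.text, key)
    last_error: Exception | None = None
    for attempt in range(cfg.max_retries):
        try:
            with urllib.request.urlopen(request, timeout=cfg.timeout) as resp:
                body = json.loads(resp.read().decode("utf-8"))
            text = _extract_text(cfg.server, body)
            if not text:
                raise BackendError(f"{cfg.server}: empty completion")
            log.debug("backend=%s task=%s ok", cfg.server, prompt.task_id)
            return LLMResponse(text=text, model_id=cfg.model_id)
        except urllib.error.HTTPError as exc:
            if exc.code == 401 or exc.code == 403:
                raise BackendError(
                    f"{cfg.server}: authentication failed (HTTP {exc.code}); "
                    "check the API key file"
                ) from exc
            if exc.code not in _RETRYABLE_STATUS:
                raise BackendError(
                    f"{cfg.server}: HTTP {exc.code} {exc.reason}"
                ) from exc
            last_error = exc
        except (urllib.error.URLError, TimeoutError) as exc:
            last_error = exc
        if attempt < cfg.max_retries - 1:
            time.sleep(2.0**attempt)
    raise BackendError(
        f"{cfg.server}: request failed after {cfg.max_retries} attempts: "
        f"{last_error}"
    )


# ---------------------------------------------------------------------------
# replay
# ---------------------------------------------------------------------------

def _load_store(cfg: BackendConfig) -> dict:
    if cfg._store_cache is not None:
        return cfg._store_cache
    store = cfg.fixture_store
    if isinstance(store, (str, Path)):
        path = Path(store)
        if not path.exists():
            raise ConfigError(f"replay fixture store not found: {path}")
        with open(path, encoding="utf-8") as fh:
            store = json.load(fh)
    if not isinstance(store, dict):
        raise ConfigError("replay fixture store must be a JSON object")
    cfg._store_cache = store
    return store


def _complete_replay(cfg: BackendConfig, prompt: AugmentedPrompt) -> LLMResponse:
    store = _load_store(cfg)
    if prompt.task_id not in store:
        raise BackendError(
            f"replay store has no fixtures for task {prompt.task_id!r}"
        )
    entry = store[prompt.task_id]
    if isinstance(entry, str):
        text = entry
    else:
        fp = prompt_fingerprint(prompt.text)
        if fp in entry:
            text = entry[fp]
        elif "default" in entry:
            text = entry["default"]
        else:
            raise BackendError(
                f"replay store for task {prompt.task_id!r} has neither a "
                f"matching fingerprint nor a default"
            )
    if not text:
        raise BackendError(f"replay fixture for {prompt.task_id!r} is empty")
    return LLMResponse(text=text, model_id=cfg.model_id, finish_reason="replay")


# ---------------------------------------------------------------------------
# HTTP request construction per server
# ---------------------------------------------------------------------------

def _build_request(cfg: BackendConfig, prompt_text: str, key: str):
    if cfg.server == "google":
        url = (
            cfg.base_url
            or "https://generativelanguage.googleapis.com/v1beta/models"
        )
        url = f"{url}/{cfg.model_id}:generateContent?key={key}"
        payload = {
            "contents": [{"parts": [{"text": prompt_text}]}],
            "generationConfig": {"temperature": cfg.temperature},
        }
        headers = {"Content-Type": "application/json"}
    elif cfg.server == "openai":
        url = (cfg.base_url or "https://api.openai.com/v1") + "/chat/completions"
        payload = {
            "model": cfg.model_id,
            "messages": [{"role": "user", "content": prompt_text}],
            "temperature": cfg.temperature,
        }
        headers = {
            "Content-Type": "application/json",
            "Authorization": f"Bearer {key}",
        }
    elif cfg.server == "ollama":
        url = (cfg.base_url or "http://localhost:11434") + "/api/generate"
        payload = {
            "model": cfg.model_id,
            "prompt": prompt_text,
            "stream": False,
            "options": {"temperature": cfg.temperature},
        }
        headers = {"Content-Type": "application/json"}
    else:  # pragma: no cover - guarded in __post_init__
        raise ConfigError(f"unknown server {cfg.server!r}")
    return urllib.request.Request(
        url, data=json.dumps(payload).encode("utf-8"), headers=headers
    )


def _extract_text(server: str, body: dict) -> str:
    try:
        if server == "google":
            return body["candidates"][0]["content"]["parts"][0]["text"]
        if server == "openai":
            return body["choices"][0]["message"]["content"]
        if server == "ollama":
            return body["response"]
    except (KeyError, IndexError, TypeError) as exc:
        raise BackendError(f"{server}: malformed response body") from exc
    raise BackendError(f"{server}: unsupported server for extraction")
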