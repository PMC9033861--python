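"""Model registry shared by the simulator, the fitter and the CLI."""

from __future__ import annotations

_REGISTRY: dict[str, object] = {}


def register(model) -> None:
    _REGISTRY[model.name] = model


def get_model(name: str):
    try:
        return _REGISTRY[name]
    except KeyError:
        known = ", ".join(sorted(_REGISTRY))
        raise ValueError(f"unknown model {name!r}; registered models: {known}") from None


def available_models() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))
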