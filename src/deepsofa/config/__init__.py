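"""Shipped default configuration tables (YAML), loadable and overridable."""

from importlib import resources

import yaml


def load_packaged_yaml(name: str) -> dict:
    """Load one of the shipped YAML config tables by file name."""
    with resources.files(__package__).joinpath(name).open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)
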