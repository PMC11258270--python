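"""Shared plumbing for the analysis scripts."""

from pathlib import Path

from gluchip.io import default_params  # noqa: F401  (re-exported)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
RESULTS.mkdir(exist_ok=True)

SEED = 1
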