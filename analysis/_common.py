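"""Shared settings for the analysis drivers: master seed and output root."""

from pathlib import Path

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"
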