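"""Regenerate the packaged default filter tap files.

Runs the deterministic Q-shift lattice design and writes every tap sequence
as a plain-text file under src/gaitdtcwt/filter_data/default/.
"""
from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from gaitdtcwt.filters import FilterPairSet, _make_default_taps, save_filter_set

if __name__ == "__main__":
    out = Path(__file__).resolve().parents[1] / "src" / "gaitdtcwt" / "filter_data" / "default"
    filters = FilterPairSet(_make_default_taps())
    save_filter_set(filters, out)
    print(f"wrote {len(filters.taps)} filter files to {out}")
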