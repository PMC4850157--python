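"""Collate the stage outputs under results/ into one summary JSON."""

import json
from pathlib import Path

from frsp.io import write_json

ROOT = Path(__file__).resolve().parent.parent / "results"

STAGES = {
    "em": ROOT / "em" / "em_stats.json",
    "frsp_target": ROOT / "frsp_target" / "stats.json",
    "frsp_sentence": ROOT / "frsp_sentence" / "stats.json",
}


def main() -> None:
    summary = {}
    for name, path in STAGES.items():
        if path.exists():
            summary[name] = json.loads(path.read_text())
            print(f"collated {name}: {path}")
        else:
            print(f"missing {name}: {path} (run the numbered script first)")
    if summary:
        write_json(ROOT / "summary.json", summary)
        print(f"wrote {ROOT / 'summary.json'}")


if __name__ == "__main__":
    main()
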