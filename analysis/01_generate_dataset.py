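"""Generate the default synthetic co-registered reading dataset.

Writes the stimulus corpus (120 sentence quadruples), every subject's
randomized trial list and simulated fixation scanpaths, and the run
configuration, under results/dataset/. The EEG sessions are simulated on the
fly by the later FRSP stages (they depend only on config + seed), so no bulky
recordings are stored here.
"""

import sys
from pathlib import Path

import numpy as np

from frsp.io import RunConfig, write_corpus_json, write_fixation_table
from frsp.pipeline import scanpaths_to_frames, simulate_dataset

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path(__file__).resolve().parent.parent / "results" / "dataset"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig()
    corpus, trials = simulate_dataset(cfg, SEED)
    fixations, trial_table = scanpaths_to_frames(corpus, trials)

    write_corpus_json(OUT / "corpus.json", corpus)
    write_fixation_table(OUT / "scanpaths.tsv", fixations)
    trial_table.to_csv(OUT / "trials.tsv", sep="\t", index=False)
    cfg.save(OUT / "config.yaml")

    lengths = [q.sentence_length for q in corpus]
    positions = [q.target_index + 1 for q in corpus]
    print(f"corpus: {len(corpus)} quadruples, "
          f"mean length {np.mean(lengths):.2f} words (SD {np.std(lengths):.2f}), "
          f"mean target position {np.mean(positions):.2f}")
    print(f"trials: {len(trials)} ({cfg.subjects} subjects x {2 * cfg.n_quads}), "
          f"{len(fixations)} fixations")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
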