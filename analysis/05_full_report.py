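#!/usr/bin/env python
"""Run the whole pipeline end to end and print the consolidated report.

Equivalent to `paleoflim report`; writes a self-contained run directory
(config snapshot, inputs, maps, masks, summaries) under results/run/.
"""

import sys

from paleoflim.pipeline import RunConfig, run_pipeline


def main() -> None:
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
    config = RunConfig(seed=seed, out_dir="results/run")
    report = run_pipeline(config)
    print(report.to_text())


if __name__ == "__main__":
    main()
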