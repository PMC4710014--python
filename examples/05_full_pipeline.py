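"""End-to-end scan on a ground-truthed synthetic dataset.

Generates a toy study (two 5 Mb chromosomes, 67 + 7 diploid samples,
coalescent background variation, two injected sweep windows, planted fixed
functional variants, one enriched pathway), runs the full pipeline, and
scores the output against the truth table.
"""

import tempfile
from pathlib import Path

from sweepscan.pipeline import RunConfig, run_scan
from sweepscan.synth import SyntheticConfig, evaluate_against_truth, generate_dataset

workdir = Path(tempfile.mkdtemp(prefix="sweepscan_demo_"))
config = SyntheticConfig(seed=7)
bundle = generate_dataset(config, workdir / "bundle")
print(f"synthetic bundle written to {bundle.root}")

result = run_scan(
    RunConfig(
        vcf=str(bundle.vcf), popmap=str(bundle.popmap),
        gff3=str(bundle.gff3), fasta=str(bundle.fasta),
        pathways=str(bundle.pathways), out_dir=str(workdir / "run"),
        window_size=config.window_size, seed=1,
    )
)
print((result.out_dir / "summary.txt").read_text())

report = evaluate_against_truth(
    bundle.truth_frame(), result.windows, result.divergent, result.enrichment
)
for key, value in report.to_dict().items():
    print(f"{key:25s} {value}")
print(
    "\nrecall/accuracy of 1.0 means every planted sweep window, fixed\n"
    "functional variant and the enriched pathway were recovered exactly."
)
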