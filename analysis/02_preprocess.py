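#!/usr/bin/env python
"""Normalise the registry: impute, categorise vitals/CCI, filter rare codes.

Reads scratch/registry.csv, drops records without a usable diagnosis,
categorises vital signs and comorbidity with the standard cutoffs, excludes
ICD-10 codes with fewer than 15 presentations, and writes the analysis-ready
registry to scratch/registry_clean.csv with the exclusion accounting in
results/filter_report.json.
"""

from pathlib import Path

from edrisk import preprocess, simulate

ROOT = Path(__file__).resolve().parents[1]

records = simulate.read_registry(ROOT / "scratch" / "registry.csv")
records, imp_log = preprocess.impute_missing(records)
records = preprocess.categorize_records(records)
clean, report = preprocess.filter_low_frequency_codes(records, min_count=15)

(ROOT / "results").mkdir(exist_ok=True)
clean.to_csv(ROOT / "scratch" / "registry_clean.csv", index=False)
report.to_json(ROOT / "results" / "filter_report.json")

print(f"records in:                {report.n_records_in:,}")
print(f"dropped (no diagnosis):    {len(imp_log.dropped):,}")
print(f"imputed cells:             {len(imp_log.imputed):,}")
print(f"excluded (<15 per code):   {report.n_records_excluded:,} "
      f"({100 * report.n_records_excluded / report.n_records_in:.2f}% of sample, "
      f"{len(report.excluded_codes)} codes)")
print(f"analysis-ready records:    {report.n_records_kept:,}")
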