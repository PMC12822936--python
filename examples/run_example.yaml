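# Validation run on the example cohort; see README for the column dictionary.
input_csv: examples/cohort_example.csv
outcome_selector: major
strata_column: inpatient
output_dir: validation_report
report_formats: [json, tsv]
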