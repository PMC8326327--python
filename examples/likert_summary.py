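"""Summarize 1-5 Likert questionnaire rows as mean +/- population SD.

The population (divide-by-n) standard deviation is the convention that
matches how usability tables in this field are typically printed.
"""

from p300tour import format_likert, summarize_likert

ROWS = {
    "Expectation": [4, 5, 5, 4, 3, 4, 5, 5, 5, 3],
    "Control":     [5, 5, 3, 5, 5, 5, 5, 3, 5, 5],
    "Follow":      [5, 3, 4, 5, 5, 3, 5, 3, 5, 4],
    "Enjoyment":   [3, 4, 1, 4, 2, 3, 4, 4, 3, 2],
}

for item, scores in ROWS.items():
    mean, sd = summarize_likert(scores)
    print(f"{item:12s} {format_likert(mean, sd)}")
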