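"""Compute a 10-point eye healthiness report for one participant.

Uses the blink rates and questionnaire answers of a 56-year-old woman who
wears contact lenses: 31 full blinks/min (> 30: 3 points), woman over 50
(1 point) and lens wear (1 point) put her in the mild dry-eye band.
"""

from blinkscore import QuestionnaireRecord, build_report
from blinkscore.detect import BlinkMetrics

metrics = BlinkMetrics(
    full_count=31, partial_count=3, duration=60.0,
    full_rate_per_min=31.0, partial_rate_per_min=3.0,
    open_close_ratio_pct=7.3,
)
questionnaire = QuestionnaireRecord(
    age=56, sex="F", dry_gritty=False, regular_contact_lens=True
)

report = build_report(metrics, questionnaire)
b = report.breakdown
print(f"blink rate points     : {b.blink_points}")
print(f"partial blink points  : {b.partial_points}")
print(f"dry/gritty points     : {b.gritty_points}")
print(f"woman over 50 points  : {b.woman_over_50_points}")
print(f"contact lens points   : {b.lens_points}")
print(f"total score           : {report.total} / 10")
print(f"category              : {report.category.value}")
print(f"alert (score >= 4)    : {report.alert}")
# totals 0-3 are normal, 4-6 mild DED (alert), 7-10 severe DED
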