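"""Replay a scripted structured interview and classify the transcript.

Feeds a fixed answer stream through the 15-question DSM-5 bank: five
symptoms affirmed (including depressed mood), duration and impairment
met, all exclusion screens answered favourably — a textbook positive.
"""

from mddtool import classify_transcript, default_bank, run_interview

bank = default_bank()

#       a1    a2    a3    a4    a5    a6    a7    a8    a9
answers = ["yes", "no", "yes", "yes", "no", "yes", "no", "no", "yes",
           "yes",  # two-week duration
           "yes",  # functional impairment
           "yes", "yes", "yes", "yes"]  # exclusion screens, all favourable

transcript, diagnosis = run_interview(bank, answers)

print(f"questions asked : {len(transcript.entries)}")
print(f"MDD screen      : {'POSITIVE' if diagnosis.mdd_positive else 'NEGATIVE'}")
for step, outcome in diagnosis.trace:
    print(f"  {step:<24} {outcome}")

# replaying the saved transcript reproduces the decision bit for bit
again = classify_transcript(bank, transcript)
print(f"replay identical: {again.mdd_positive == diagnosis.mdd_positive}")

# a double denial of the core symptoms ends the interview after 2 questions
short, verdict = run_interview(bank, ["no", "no"])
print(f"core screen-out : {len(short.entries)} questions, "
      f"{'POSITIVE' if verdict.mdd_positive else 'NEGATIVE'}")
# The trace shows each criterion checked; the screen-out path shows the
# early-exit rule sparing respondents 13 questions that cannot change the
# outcome.
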