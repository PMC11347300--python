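"""Build the RSVP stimulus schedule and assign photograph pools.

The protocol hides one familiar face (target) among nine stranger faces
(nontargets) per 2-s trial; five trials per 20-s block, ten blocks, 245 s of
core task.  Nontarget photographs are never repeated so strangers cannot
become familiar through exposure.
"""
import pupilgate as pg

config = pg.ParadigmConfig()
schedule = pg.build_schedule(config, seed=1)

print(f"trial duration    : {config.trial_duration / 1000:.0f} s")
print(f"block duration    : {config.block_duration / 1000:.0f} s")
print(f"core task duration: {schedule.core_duration / 1000:.0f} s")
print(f"events            : {len(schedule.events)} "
      f"({schedule.n_targets} targets, {schedule.n_nontargets} nontargets)")

targets = [f"familiar_{i:02d}" for i in range(10)]
nontargets = [f"stranger_{i:03d}" for i in range(900)]
assigned = pg.assign_stimuli(schedule, targets, nontargets, seed=1)

table = pg.events_to_table(assigned)
print("\nfirst trial:")
print(table.head(10).to_string(index=False))
# Each row is one 100 ms photograph flash (onsets 200 ms apart); exactly one
# row per trial is the target, and every stranger id appears at most once.
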