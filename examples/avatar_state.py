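"""Compute a future-self avatar state from steps and purchase history.

Uses the synthetic generator for one participant, then maps the five
features (fitness, heart health, mental well-being, bone health, blood
sugar) onto 1..5 states and prints the feedback a user would see.
"""

import datetime as dt

from nutribasket import CohortConfig, compute_avatar_state, feedback_message
from nutribasket import generate_catalog, generate_participant

config = CohortConfig(n_products=500)
catalog = generate_catalog(n_products=500, n_categories=125, seed=8)
person = generate_participant(config, "intervention", catalog, seed=8, participant_id="demo")

as_of = config.start_date + dt.timedelta(days=35)
state = compute_avatar_state(person.steps, person.baskets, catalog, as_of, user_age=44)

print(f"avatar age: {state.avatar_age:.0f} (user is 44; the avatar shows +20 years)")
for name, feat in state.features.items():
    driver = "no data" if feat.driver is None else f"{feat.driver:,.1f}"
    print(f"{name:17s} driver={driver:>9s} state={feat.state} | {feedback_message(feat)[:72]}...")
# States run 1 (worst) to 5 (best); fitness follows the 7-day step mean,
# the nutritional features follow 12-basket FSA-NPS component-point means.
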