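"""From questionnaire answers to daily omega-3 and energy intake.

One participant answers the food-frequency questionnaire: for each food,
how often they ate it and how large the portion was.  The engine converts
each answer to grams per day via the composition table and sums nutrient
contributions.
"""

from omegadose import CompositionTable, FFQResponse, total_intake

table = CompositionTable.default()
print(f"composition table: {len(table)} items, e.g. {table.item_ids[:5]}")

response = FFQResponse(
    items={
        "salmon": ("3-4_per_week", "medium"),
        "mackerel": ("1-2_per_week", "large"),
        "saury": ("1-3_per_month", "medium"),
        "rice": ("2-3_per_day", "medium"),
        "tofu": ("daily", "small"),
    }
)

omega3, energy = total_intake(response, table)
print(f"omega-3 intake: {omega3:.3f} g/day")
print(f"energy intake:  {energy:.0f} kcal/day")

# portion size scales intake linearly: the same answers with large portions
large = FFQResponse(items={k: (f, "large") for k, (f, _) in response.items.items()})
omega3_large, _ = total_intake(large, table)
print(f"all-large portions: {omega3_large:.3f} g/day")
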