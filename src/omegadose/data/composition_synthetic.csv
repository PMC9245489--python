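item_id,name,group,standard_portion_g,omega3_g_per_100g,energy_kcal_per_100g
salmon,Salmon (grilled),fish,80,2.10,200
mackerel,Mackerel,fish,80,2.60,240
saury,Pacific saury,fish,100,3.80,310
sardine,Sardine,fish,60,2.10,190
pilchard_dried,Dried pilchard,fish,30,3.30,330
tuna_lean,Tuna (lean sashimi),fish,60,0.30,110
tuna_fatty,Tuna (fatty sashimi),fish,50,3.20,340
tuna_canned,Canned tuna,fish,40,0.90,270
yellowtail,Yellowtail,fish,80,1.70,260
horse_mackerel,Horse mackerel,fish,70,1.10,120
sea_bream,Sea bream,fish,80,0.90,140
cod,Cod,fish,80,0.20,80
eel,Eel (kabayaki),fish,80,2.40,290
whitebait_dried,Dried whitebait,fish,10,1.40,210
salmon_roe,Salted salmon roe,fish,20,4.80,270
squid,Squid,shellfish,60,0.40,85
octopus,Octopus,shellfish,60,0.20,75
shrimp,Shrimp,shellfish,50,0.30,90
crab,Crab,shellfish,50,0.40,65
scallop,Scallop,shellfish,50,0.40,90
oyster,Oyster,shellfish,60,0.70,70
rice,Cooked rice,staple,150,0.00,168
bread,Bread,staple,60,0.02,260
noodles,Noodles,staple,200,0.01,130
beef,Beef,meat,80,0.03,250
pork,Pork,meat,80,0.04,240
chicken,Chicken,meat,80,0.03,200
eggs,Hen egg,other,50,0.08,150
tofu,Tofu,other,100,0.15,75
milk,Milk,other,200,0.01,65
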