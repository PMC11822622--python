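keyword,tags
apple,fruit
banana,fruit
orange,fruit
pear,fruit
melon,fruit
grapes,fruit
fruit,fruit
fruit salad,fruit
fruit pot,fruit
carrot,vegetable
carrots,vegetable
peas,vegetable
broccoli,vegetable
sweetcorn,vegetable
beetroot,vegetable
vegetable,vegetable
vegetables,vegetable
salad,salad
coleslaw,salad
cod,fish
haddock,fish
fish,fish
tuna,fish;oily_fish
salmon,fish;oily_fish
mackerel,fish;oily_fish
sardines,fish;oily_fish
beef,red_meat
lamb,red_meat
pork,red_meat
steak,red_meat;meat_cut
gammon,red_meat;processed_meat
ham,red_meat;processed_meat
bacon,processed_meat;red_meat
sausage,processed_meat
sausages,processed_meat
hot dog,processed_meat
pepperoni,processed_meat
nuggets,processed_meat
chicken popcorn,processed_meat;poultry
popcorn chicken,processed_meat;poultry
chicken,poultry
turkey,poultry
roast,meat_cut
bean,non_meat_protein
beans,non_meat_protein
lentil,non_meat_protein
lentils,non_meat_protein
chickpea,non_meat_protein
chickpeas,non_meat_protein
quorn,non_meat_protein
tofu,non_meat_protein;vegan_alternative
jackfruit,non_meat_protein;vegan_alternative
vegan,vegan_alternative
potato,potato
potatoes,potato
chips,potato
wedges,potato
mash,potato
pasta,non_potato_starch
penne,non_potato_starch
rice,non_potato_starch
noodles,non_potato_starch
couscous,non_potato_starch
bread,bread
baguette,bread
roll,bread
bap,bread
panini,bread
sandwich,bread
toast,bread
wrap,bread
wholemeal,wholegrain
wholegrain,wholegrain
brown rice,wholegrain;non_potato_starch
porridge,wholegrain
oats,wholegrain
milk,milk
semi skimmed,lower_fat_milk
skimmed,lower_fat_milk
soya milk,non_dairy_milk
oat milk,non_dairy_milk
yogurt,yogurt
yoghurt,yogurt
low sugar yogurt,yogurt;low_sugar_yogurt
low sugar yoghurt,yogurt;low_sugar_yogurt
chocolate,hfss_confectionery
sweets,hfss_confectionery
candy,hfss_confectionery
crisps,hfss_savoury
biscuit,hfss_sweet_snack
biscuits,hfss_sweet_snack
cookie,hfss_sweet_snack
cookies,hfss_sweet_snack
flapjack,hfss_sweet_snack
muffin,hfss_sweet_snack
cake,hfss_sweet_snack
cakes,hfss_sweet_snack
traybake,hfss_sweet_snack
pastry,hfss_sweet_snack
doughnut,hfss_sweet_snack
oatcake,compliant_snack
oatcakes,compliant_snack
rice cakes,compliant_snack
breadsticks,compliant_snack
water,drink
juice,drink
drink,drink
cola,drink
smoothie,drink
diet,sugar_info_present
sugar free,sugar_info_present
no added sugar,sugar_info_present
salt,salt_sachet
salt sachet,salt_sachet
ketchup,condiment
mayonnaise,condiment
butter,condiment
margarine,condiment
gravy,condiment
meal of the day,meal_of_day
meal deal,meal_deal
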