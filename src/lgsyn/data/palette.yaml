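# Hierarchical food palette for the category-matching consistency test:
# 11 superordinate categories, 87 subordinate foods.  Derived from the DAFNE
# (Data Food Networking) food classification, adapted toward the food
# experiences typically reported by lexical-gustatory synesthetes (expanded
# sugar products; a nonfood/texture branch for inedible concurrents).
categories:
  - name: Bakery/Cereals
    foods:
      - Bread and rolls
      - Other bakery products
      - Flour
      - Pastry
      - Pasta
      - Breakfast cereals
      - Rice/other cereals (excl. sweet corn)
  - name: Meat/Meat Products
    foods:
      - Pork/bacon
      - Beef/veal
      - Other red meat
      - Offal
      - Poultry
      - Meat products (e.g., sausage; canned)
      - Other meat dishes
  - name: Fish/Seafood
    foods:
      - Fish, fresh/frozen/processed (e.g., tinned)
      - Seafood
      - Fish dishes (e.g., breaded fish)
  - name: Eggs/Dairy
    foods:
      - Eggs
      - Milk
      - Cheese
      - Other milk products (e.g., Yoghurt)
  - name: Fats
    foods:
      - Butter
      - Other animal fat
      - Vegetable fat (e.g., margarine)
      - Vegetable oil (e.g., olive, sesame)
  - name: Sugar/Sugar Products
    foods:
      - Sugar
      - Chocolate
      - Sweets/Candy
      - Artificial sweetener
      - Other sugar products
  - name: Vegetables (incl. Pulses, Potatoes)
    foods:
      - Cabbage
      - Other green leafy
      - Cucumber
      - Tomatoes
      - Carrots
      - Mushrooms
      - Peppers/chilis
      - Squash (e.g., pumpkin)
      - Broccoli
      - Onions/garlic/leek
      - Potatoes/other starchy root
      - Beans (e.g., green, baked)
      - Other pulses (e.g., peas, lentils)
      - Other vegetables (incl. sweet corn)
  - name: Fruits and Nuts
    foods:
      - Apples
      - Citrus
      - Bananas
      - Grapes
      - Plums
      - Berries (e.g., strawberry)
      - Apricots/peaches
      - Cherries
      - Pears
      - Nuts or peanuts
      - Dried/processed fruits
      - Other fresh fruits
  - name: Condiments/Sauces/Soups
    foods:
      - Salt
      - Pepper
      - Vinegar
      - Mustard
      - Mayonnaise
      - Meat Juice and extracts
      - Vegetable extracts (e.g., marmite)
      - Herbs (fresh or dried)
      - Dried spices (e.g., paprika)
      - Soup
      - Other sauces (wet)
      - Other condiments (dry)
  - name: Beverages
    foods:
      - Coffee
      - Tea
      - Cocoa
      - Water
      - Fruit/vegetable juice
      - Other soft drink (excl. milk)
      - Wine
      - Beer
      - Spirit
  - name: Nonfoods/Inedibles/Textures
    foods:
      - Medication
      - Organic (e.g., earwax)
      - Inorganic/chemical (e.g., plastics)
      - "Texture: Rough/hard/crunchy"
      - "Texture: Smooth/soft/chewy"
      - "Temperature: Warm/hot"
      - "Temperature: cold"
      - "Shape: Nonfood"
      - Other (e.g., an action)
      - Distinct but cannot identify
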