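# Synthetic 30-word stimulus list (placeholder instrument).
# The published instrument uses 30 high-frequency, early-acquired English
# words; that list is not redistributed here, so this file ships a synthetic
# stand-in with the same shape (30 common, early-acquired English words).
# Scoring is word-list agnostic: any list of n >= 1 unique words is accepted.
door
table
window
garden
summer
morning
paper
letter
water
mother
school
street
winter
evening
market
river
mountain
dinner
music
question
distance
reason
society
audience
child
friend
house
corner
picture
village
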