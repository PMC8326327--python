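{
  "Europe": ["Paris", "London", "Rome", "Barcelona", "Iceland", "Firenze"],
  "Asia": ["Seoul", "Dubai", "Hongkong", "India", "Tokyo", "Shanghai"],
  "North America": ["Vancouver", "New York", "Las Vegas", "Los Angeles", "Chicago", "Alaska"],
  "Oceania": ["Sydney", "Melbourne", "Fiji", "New Zealand", "Papua New Guinea", "Vanuatu"],
  "South America": ["Barbados", "Easter Island", "Patagonia", "Cusco", "Rio de Janeiro", "Buenos Aires"],
  "Africa": ["Egypt", "Cape Town", "Johannesburg", "Nairobi", "Pretoria East", "Ethiopia"]
}
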