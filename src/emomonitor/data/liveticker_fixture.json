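{
  "liveticker_id": "lt-demo-001",
  "title": "Synthetic liveticker replay fixture",
  "platform": "derstandard",
  "items": [
    {
      "id": "item-001",
      "timestamp": "2020-03-16T08:00:00+01:00",
      "headline": "Erste Meldung des Tages",
      "posts": [
        {
          "id": "p-0001",
          "author": "user-a",
          "timestamp": "2020-03-16T08:01:30+01:00",
          "text": "Ich habe große Angst vor dem, was kommt."
        },
        {
          "id": "p-0002",
          "author": "user-b",
          "timestamp": "2020-03-16T08:05:12+01:00",
          "text": "Bleibt zuhause und helft einander! #solidarität"
        }
      ]
    },
    {
      "id": "item-002",
      "timestamp": "2020-03-16T09:30:00+01:00",
      "headline": "Zweite Meldung",
      "posts": [
        {
          "id": "p-0003",
          "author": "user-c",
          "timestamp": "2020-03-16T09:31:05+01:00",
          "text": "Gute Besserung an alle Betroffenen @user https://example.org/x"
        }
      ]
    },
    {
      "id": "item-003",
      "timestamp": "2020-03-16T11:00:00+01:00",
      "headline": "Leere Diskussion",
      "posts": []
    }
  ]
}
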